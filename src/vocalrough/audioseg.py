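"""Syllable and bout segmentation of vocalization recordings.

A syllable is a maximal region where the smoothed rectified-signal envelope
stays at or above a threshold expressed as a fraction of digital full scale
(default 4.1%), with sub-threshold runs shorter than a minimum gap (default
1 ms) bridged.  The threshold is referenced to full scale — the fixed
maximum of the recording chain — not to the per-file maximum, so detection
is deliberately sensitive to absolute level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .waveform import Waveform


@dataclass
class SyllableSegment:
    """One detected vocal unit, a half-open [start_s, end_s) slice."""

    source: str
    start_s: float
    end_s: float
    samples: np.ndarray
    rate_hz: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def waveform(self) -> Waveform:
        return Waveform(self.samples, self.rate_hz)


@dataclass
class Bout:
    """A group of syllables separated by gaps below the bout threshold."""

    segments: list
    gap_threshold_s: float

    def __len__(self) -> int:
        return len(self.segments)


def _detection_envelope(x: np.ndarray, rate_hz: float, smooth_s: float = 0.0001) -> np.ndarray:
    """Peak-tracking envelope: running maximum of |x| over ``smooth_s``.

    A running maximum (rather than a moving average) keeps the envelope on
    the amplitude scale the threshold refers to — an averaged rectified
    carrier would read ~0.64x the true amplitude and shift the effective
    threshold.
    """
    win = max(int(round(smooth_s * rate_hz)), 1)
    return ndimage.maximum_filter1d(np.abs(x), size=win, mode="nearest")


def segment_syllables(
    rec: Waveform,
    threshold_frac: float = 0.041,
    min_gap_s: float = 0.001,
    min_dur_s: float = 0.0005,
    source: str = "",
) -> list[SyllableSegment]:
    """Detect syllables by amplitude thresholding of the envelope.

    Parameters
    ----------
    rec
        The recording; samples are full-scale amplitudes (|x| <= 1).
    threshold_frac
        Detection threshold as a fraction of full scale (default 0.041).
    min_gap_s
        Sub-threshold runs shorter than this are bridged into the
        surrounding syllable (default 1 ms).
    min_dur_s
        Detected regions shorter than this are dropped as clicks
        (default 0.5 ms) — an automatic stand-in for manual revision.
    """
    if rec.n == 0:
        raise ValueError("empty recording")
    env = _detection_envelope(rec.samples, rec.rate_hz)
    above = env >= threshold_frac
    if not above.any():
        return []

    # bridge sub-threshold runs shorter than min_gap_s
    labels, n_runs = ndimage.label(~above)
    if n_runs:
        min_gap_n = int(round(min_gap_s * rec.rate_hz))
        run_slices = ndimage.find_objects(labels)
        for sl in run_slices:
            s = sl[0]
            interior = s.start > 0 and s.stop < above.size
            if interior and (s.stop - s.start) < min_gap_n:
                above[s] = True

    seg_labels, n_segs = ndimage.label(above)
    min_dur_n = int(round(min_dur_s * rec.rate_hz))
    out = []
    for sl in ndimage.find_objects(seg_labels):
        s = sl[0]
        if (s.stop - s.start) < min_dur_n:
            continue
        out.append(
            SyllableSegment(
                source=source,
                start_s=s.start / rec.rate_hz,
                end_s=s.stop / rec.rate_hz,
                samples=rec.samples[s].copy(),
                rate_hz=rec.rate_hz,
            )
        )
    return out


def group_bouts(segments: list, bout_gap_s: float = 0.030) -> list:
    """Group time-ordered syllable segments into multi-syllabic bouts.

    Consecutive segments whose offset-to-onset gap is at most
    ``bout_gap_s`` share a bout.
    """
    if not segments:
        return []
    bouts = [Bout([segments[0]], bout_gap_s)]
    for prev, cur in zip(segments, segments[1:]):
        if cur.start_s - prev.end_s <= bout_gap_s:
            bouts[-1].segments.append(cur)
        else:
            bouts.append(Bout([cur], bout_gap_s))
    return bouts
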