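"""Synthetic generators for every input the analysis pipeline consumes.

The generators emulate the statistical structure of *Carollia perspicillata*
distress vocalizations and the physiological recordings made while bats
listened to them: harmonically structured downward-FM syllables with or
without sinusoidal amplitude modulation near 1.7 kHz, bouted stimulus
sequences (11 bouts x 6 syllables, 14 ms inter-syllable and 80 ms inter-bout
silent gaps), ECG traces whose post-stimulus heart-rate acceleration depends
on the stimulus, iEEG traces carrying a stimulus-locked frequency-following
component, and two-tone ear-canal epochs with a planted cubic distortion
product.  Every generator returns machine-readable ground truth so that the
analysis modules can be tested as parameter-recovery problems.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .waveform import Waveform

FM = "FM"
QCF_FM = "qCF-FM"
SFM = "SFM"

_VARIANTS = (FM, QCF_FM, SFM)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class SyllableSpec:
    """Parameters of one synthetic distress syllable.

    The carrier is a harmonic stack whose fundamental sweeps downward
    (``FM``), holds a quasi-constant-frequency plateau before sweeping
    (``qCF-FM``), or oscillates sinusoidally (``SFM``).  ``am_rate_hz`` > 0
    adds a sinusoidal amplitude modulation — the roughness-like structure.
    """

    duration_s: float = 0.005
    fundamental_start_hz: float = 28000.0
    fundamental_end_hz: float = 18000.0
    n_harmonics: int = 3
    am_rate_hz: float = 1700.0
    am_depth: float = 0.9
    fm_variant: str = FM
    ramp_s: float = 0.0003
    rate_hz: float = 300000.0
    # qCF-FM: fraction of the duration spent on the initial plateau
    qcf_plateau_frac: float = 0.4
    # SFM: rate and depth of the sinusoidal frequency trajectory
    sfm_rate_hz: float = 500.0
    sfm_depth_hz: float = 5000.0

    def validate(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not 0.0 <= self.am_depth <= 1.0:
            raise ValueError("am_depth must be in [0, 1]")
        if self.fm_variant not in _VARIANTS:
            raise ValueError(f"fm_variant must be one of {_VARIANTS}")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        fmax = self._max_fundamental() * self.n_harmonics
        if fmax >= self.rate_hz / 2:
            raise ValueError(
                f"highest harmonic ({fmax:.0f} Hz) is at or above Nyquist "
                f"({self.rate_hz / 2:.0f} Hz); lower n_harmonics or the sweep"
            )
        # the envelope is later sampled at 0.1 ms — the modulator must be
        # representable there
        if self.am_rate_hz >= 5000.0:
            raise ValueError("am_rate_hz must lie below 5 kHz")

    def _max_fundamental(self) -> float:
        top = max(self.fundamental_start_hz, self.fundamental_end_hz)
        if self.fm_variant == SFM:
            mid = 0.5 * (self.fundamental_start_hz + self.fundamental_end_hz)
            top = max(top, mid + self.sfm_depth_hz)
        return top


@dataclass
class SequenceLayout:
    """Bout/gap geometry of a playback stimulus sequence.

    Gaps are silent offset-to-onset intervals: an 80 ms onset-to-onset
    inter-bout interval could not contain a six-syllable bout, so the
    printed 14/80 ms values are read as silences between sounds.
    """

    n_bouts: int = 11
    syllables_per_bout: int = 6
    isi_s: float = 0.014
    ibi_s: float = 0.080
    fade_s: float = 0.0002
    # "gaps": isi/ibi are silent gaps; "onset": onset-to-onset intervals
    gap_mode: str = "gaps"

    def validate(self) -> None:
        if self.n_bouts < 1 or self.syllables_per_bout < 1:
            raise ValueError("counts must be >= 1")
        if self.isi_s < 0 or self.ibi_s < 0 or self.fade_s < 0:
            raise ValueError("gaps and fades must be >= 0")
        if self.gap_mode not in ("gaps", "onset"):
            raise ValueError("gap_mode must be 'gaps' or 'onset'")


@dataclass
class CorpusSpec:
    """Parameters of a synthetic vocalization corpus.

    ``fam_fraction`` is the planted probability that a syllable is a fast
    amplitude-modulated vocalization (fAMV); ``position_bias`` > 0 shifts
    fAMVs toward the first half of each sequence.
    """

    n_sequences: int = 50
    syllables_median: float = 60.0
    syllables_sigma: float = 0.3
    fam_fraction: float = 0.477
    position_bias: float = 0.0
    am_rate_center_hz: float = 1750.0
    am_rate_spread_hz: float = 200.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.fam_fraction <= 1.0:
            raise ValueError("fam_fraction must be in [0, 1]")
        if self.position_bias < 0:
            raise ValueError("position_bias must be >= 0")
        if self.n_sequences < 0:
            raise ValueError("n_sequences must be >= 0")


@dataclass
class EcgTrialSpec:
    """Parameters of one synthetic ECG trial around a stimulus onset."""

    rate_hz: float = 9600.0
    pre_s: float = 5.0
    post_s: float = 10.0
    baseline_bpm: float = 480.0
    response_gain_bpm: float = 0.0
    rise_s: float = 0.5
    decay_s: float = 2.0
    qrs_polarity: int = -1
    noise_sd: float = 0.05
    artifact_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.baseline_bpm > 0:
            raise ValueError("baseline_bpm must be positive")
        if self.qrs_polarity not in (-1, 1):
            raise ValueError("qrs_polarity must be -1 or +1")
        if self.baseline_bpm + min(0.0, self.response_gain_bpm) <= 0:
            raise ValueError("instantaneous rate must stay positive")


@dataclass
class IeegTrialSpec:
    """Parameters of one synthetic iEEG trial."""

    rate_hz: float = 9600.0
    ffr_gain: float = 0.0
    evoked_gain: float = 1.0
    noise_exponent: float = 1.0
    silent_baseline_s: float = 1.5
    post_s: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.silent_baseline_s < 1.5:
            raise ValueError("silent_baseline_s must be >= 1.5 s")


@dataclass
class EarCanalSpec:
    """Two-tone ear-canal stimulation parameters for DPOAE emulation.

    ``f1_hz`` defaults to ``f2_hz / 1.25`` (the fixed f2/f1 ratio).  A cubic
    distortion product at 2*f1 - f2 is planted at ``dp_level_db`` only when
    f2 lies at or above ``cochlear_cutoff_hz`` — emulating a cochlea whose
    nonlinear amplification deteriorates below 5 kHz.
    """

    f2_hz: float = 18000.0
    f1_hz: float | None = None
    l1_db: float = 60.0
    l2_db: float = 50.0
    dp_level_db: float = 25.0
    cochlear_cutoff_hz: float = 5000.0
    epoch_len: int = 8192
    n_epochs: int = 100
    rate_hz: float = 192000.0
    noise_db: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f1_hz is None:
            self.f1_hz = self.f2_hz / 1.25

    def validate(self) -> None:
        if abs(self.f2_hz / self.f1_hz - 1.25) > 1e-9:
            raise ValueError("f2/f1 must equal 1.25")
        if 2 * self.f1_hz - self.f2_hz <= 0:
            raise ValueError("cubic DP frequency must be positive")
        if self.epoch_len < 2 or self.n_epochs < 1:
            raise ValueError("epoch geometry invalid")

    @property
    def dp_hz(self) -> float:
        return 2 * self.f1_hz - self.f2_hz


# ---------------------------------------------------------------------------
# Syllables and tones
# ---------------------------------------------------------------------------

def _fundamental_trajectory(spec: SyllableSpec, t: np.ndarray) -> np.ndarray:
    d = spec.duration_s
    f0, f1 = spec.fundamental_start_hz, spec.fundamental_end_hz
    if spec.fm_variant == FM:
        return f0 + (f1 - f0) * t / d
    if spec.fm_variant == QCF_FM:
        t_plateau = spec.qcf_plateau_frac * d
        freq = np.full_like(t, f0)
        sweep = t >= t_plateau
        span = max(d - t_plateau, np.finfo(float).tiny)
        freq[sweep] = f0 + (f1 - f0) * (t[sweep] - t_plateau) / span
        return freq
    # SFM: carrier oscillates around the band midpoint
    mid = 0.5 * (f0 + f1)
    return mid + spec.sfm_depth_hz * np.sin(2 * np.pi * spec.sfm_rate_hz * t)


def _linear_ramps(n: int, n_ramp: int) -> np.ndarray:
    env = np.ones(n)
    n_ramp = min(n_ramp, n // 2)
    if n_ramp > 0:
        ramp = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


def make_syllable(spec: SyllableSpec, seed: int = 0) -> tuple[Waveform, dict]:
    """Render one syllable and its planted ground truth.

    The instantaneous amplitude is
    ``carrier * (1 + am_depth*sin(2*pi*am_rate_hz*t + phi)) / (1 + am_depth)``
    with linear onset/offset ramps; the (1 + depth) normalization keeps the
    peak amplitude depth-invariant so that level comparisons stay about
    modulation, not gain.  The waveform is peak-normalized to 1.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * spec.rate_hz))
    t = np.arange(n) / spec.rate_hz

    freq = _fundamental_trajectory(spec, t)
    phase0 = 2 * np.pi * np.cumsum(freq) / spec.rate_hz
    carrier = np.zeros(n)
    for k in range(1, spec.n_harmonics + 1):
        carrier += (1.0 / k) * np.sin(k * phase0 + rng.uniform(0, 2 * np.pi))

    am_phase = rng.uniform(0, 2 * np.pi)
    if spec.am_rate_hz > 0:
        modulator = (
            1.0 + spec.am_depth * np.sin(2 * np.pi * spec.am_rate_hz * t + am_phase)
        ) / (1.0 + spec.am_depth)
    else:
        modulator = np.ones(n)

    x = carrier * modulator * _linear_ramps(n, int(round(spec.ramp_s * spec.rate_hz)))
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak

    truth = {
        "am_rate_hz": float(spec.am_rate_hz),
        "am_depth": float(spec.am_depth if spec.am_rate_hz > 0 else 0.0),
        "fm_variant": spec.fm_variant,
        "am_phase": float(am_phase),
        "duration_s": float(spec.duration_s),
    }
    return Waveform(x, spec.rate_hz), truth


def shallow_fm_syllable_spec(
    am_rate_hz: float,
    am_depth: float = 0.9,
    duration_s: float = 0.006,
    rate_hz: float = 300000.0,
) -> SyllableSpec:
    """Spec for a shallow-sweep rough syllable with well-defined sidebands.

    Spectral AM sidebands are resolvable as a comb only when the carrier
    line width (sweep extent plus 1/duration) stays comfortably below the
    AM rate; a steep sweep instead produces envelope imaging at
    sweep_rate / am_rate spacing.  This spec uses a 500 Hz terminal sweep
    (28 -> 27.5 kHz), placing the syllable firmly in the sideband regime —
    the regime in which spectral regularity mirrors the modulation rate.
    """
    return SyllableSpec(
        duration_s=duration_s,
        fundamental_start_hz=28000.0,
        fundamental_end_hz=27500.0,
        am_rate_hz=am_rate_hz,
        am_depth=am_depth,
        rate_hz=rate_hz,
    )


def make_am_tone(
    carrier_hz: float, am_rate_hz: float, duration_s: float, rate_hz: float
) -> Waveform:
    """Sinusoidally amplitude-modulated pure tone at full modulation depth.

    ``am_rate_hz = 0`` yields an unmodulated tone.  The waveform is
    peak-normalized.
    """
    if carrier_hz >= rate_hz / 2:
        raise ValueError("carrier must lie below Nyquist")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    x = np.sin(2 * np.pi * carrier_hz * t)
    if am_rate_hz > 0:
        x = x * (1.0 + np.sin(2 * np.pi * am_rate_hz * t)) / 2.0
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    return Waveform(x, rate_hz)


# ---------------------------------------------------------------------------
# Corpora
# ---------------------------------------------------------------------------

def _corpus_positions(rng, n_syll: int, n_fast: int, bias: float) -> np.ndarray:
    """Pick the slots for fast-AM syllables, optionally biased leftward.

    With ``bias = 0`` placement is uniform; bias > 0 weights slot i by
    exp(-bias * normalized_position).
    """
    if n_fast == 0:
        return np.zeros(n_syll, dtype=bool)
    pos = np.arange(n_syll)
    norm = pos / (n_syll - 1) if n_syll > 1 else np.array([0.5])
    w = np.exp(-bias * norm)
    chosen = rng.choice(pos, size=n_fast, replace=False, p=w / w.sum())
    mask = np.zeros(n_syll, dtype=bool)
    mask[chosen] = True
    return mask


def make_distress_corpus(spec: CorpusSpec) -> tuple[list[Waveform], pd.DataFrame]:
    """Generate a corpus of bouted vocalization sequences with ground truth.

    Each sequence draws its syllable count log-normally (median
    ``syllables_median``), assigns fast-AM labels with probability
    ``fam_fraction`` (placement optionally position-biased), renders each
    syllable, and arranges them in bouts of 3-8 with 14 ms within-bout and
    80 ms between-bout silent gaps.  Fast-AM syllables carry AM at rates
    drawn around ``am_rate_center_hz`` with depths 0.7-1.0; slow-AM
    syllables carry no modulation in the 1.15-2.45 kHz band (either none at
    all or a slow wobble below 400 Hz).

    Returns the sequence waveforms and a per-syllable ground-truth table
    with columns sequence, index, onset_s, label, am_rate_hz, am_depth,
    norm_position.
    """
    spec.validate()
    if spec.n_sequences == 0:
        import warnings

        warnings.warn("empty corpus requested")
        return [], pd.DataFrame(
            columns=[
                "sequence", "index", "onset_s", "label",
                "am_rate_hz", "am_depth", "norm_position",
            ]
        )
    rng = np.random.default_rng(spec.seed)
    sequences: list[Waveform] = []
    rows = []
    rate = 300000.0
    for s_idx in range(spec.n_sequences):
        n_syll = max(
            2,
            int(round(
                np.exp(np.log(spec.syllables_median)
                       + spec.syllables_sigma * rng.standard_normal())
            )),
        )
        n_fast = rng.binomial(n_syll, spec.fam_fraction)
        fast_mask = _corpus_positions(rng, n_syll, n_fast, spec.position_bias)

        pieces = []
        cursor = 0
        next_bout_break = rng.integers(3, 9)
        for i in range(n_syll):
            dur = rng.uniform(0.004, 0.008)
            if fast_mask[i]:
                rate_am = float(np.clip(
                    rng.normal(spec.am_rate_center_hz, spec.am_rate_spread_hz),
                    1200.0, 2400.0,
                ))
                depth = rng.uniform(0.7, 1.0)
            else:
                # half the slow syllables are fully unmodulated, half carry a
                # slow (< 400 Hz) wobble well outside the FOI band
                if rng.random() < 0.5:
                    rate_am, depth = 0.0, 0.0
                else:
                    rate_am = rng.uniform(50.0, 400.0)
                    depth = rng.uniform(0.1, 0.5)
            syl_spec = SyllableSpec(
                duration_s=dur, am_rate_hz=rate_am, am_depth=depth, rate_hz=rate
            )
            wave, _ = make_syllable(syl_spec, seed=int(rng.integers(0, 2**31)))
            samples = wave.samples * 0.5  # peaks at 50% full scale
            onset_s = cursor / rate
            pieces.append(samples)
            cursor += samples.size
            if i < n_syll - 1:
                gap = 0.080 if (i + 1) % next_bout_break == 0 else 0.014
                gap_n = int(round(gap * rate))
                pieces.append(np.zeros(gap_n))
                cursor += gap_n
            norm_pos = (i / (n_syll - 1)) if n_syll > 1 else 0.5
            rows.append({
                "sequence": s_idx,
                "index": i,
                "onset_s": onset_s,
                "label": "fAMV" if fast_mask[i] else "sAMV",
                "am_rate_hz": rate_am,
                "am_depth": depth,
                "norm_position": norm_pos,
            })
        sequences.append(Waveform(np.concatenate(pieces), rate))
    return sequences, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stimulus sequences
# ---------------------------------------------------------------------------

def make_stimulus_sequence(
    syllable: Waveform, layout: SequenceLayout | None = None
) -> tuple[Waveform, np.ndarray]:
    """Repeat one syllable in a bouted playback sequence.

    Returns the concatenated waveform and the onset time (s) of every
    syllable copy.  Each copy is edge-faded over ``fade_s``; the output is
    RMS-normalized to the RMS of the faded syllable stream (gaps excluded
    from the reference, as silence carries no level information).
    """
    layout = layout or SequenceLayout()
    layout.validate()
    rate = syllable.rate_hz
    syl = syllable.samples.copy()
    n_fade = int(round(layout.fade_s * rate))
    if n_fade > syl.size // 2:
        raise ValueError("fade longer than half the syllable")
    syl *= _linear_ramps(syl.size, n_fade)

    syl_dur = syl.size / rate
    if layout.gap_mode == "gaps":
        isi_gap, ibi_gap = layout.isi_s, layout.ibi_s
    else:  # onset-to-onset intervals
        isi_gap = max(layout.isi_s - syl_dur, 0.0)
        ibi_gap = max(layout.ibi_s - syl_dur, 0.0)

    pieces = []
    onsets = []
    cursor = 0
    isi_n = int(round(isi_gap * rate))
    ibi_n = int(round(ibi_gap * rate))
    for b in range(layout.n_bouts):
        for s in range(layout.syllables_per_bout):
            onsets.append(cursor / rate)
            pieces.append(syl)
            cursor += syl.size
            last_in_bout = s == layout.syllables_per_bout - 1
            last_overall = last_in_bout and b == layout.n_bouts - 1
            if not last_overall:
                gap_n = ibi_n if last_in_bout else isi_n
                pieces.append(np.zeros(gap_n))
                cursor += gap_n
    out = np.concatenate(pieces)
    syl_rms = np.sqrt(np.mean(syl**2))
    out_stream_rms = np.sqrt(
        np.mean(np.concatenate([syl] * (layout.n_bouts * layout.syllables_per_bout)) ** 2)
    )
    if out_stream_rms > 0:
        out *= syl_rms / out_stream_rms
    return Waveform(out, rate), np.asarray(onsets)


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def _hr_kernel(tau: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Causal rise/decay heart-rate response kernel, peak-normalized."""
    g = np.where(
        tau >= 0, (1.0 - np.exp(-np.maximum(tau, 0) / rise_s)) * np.exp(-np.maximum(tau, 0) / decay_s), 0.0
    )
    peak = g.max() if g.size else 0.0
    return g / peak if peak > 0 else g


def _qrs_template(rate_hz: float, polarity: int) -> np.ndarray:
    """A ~10 ms biphasic QRS-like deflection with a dominant lobe."""
    n = int(round(0.010 * rate_hz))
    t = (np.arange(n) - n // 2) / rate_hz
    sharp = np.exp(-0.5 * (t / 0.0012) ** 2)
    counter = 0.35 * np.exp(-0.5 * ((t - 0.003) / 0.002) ** 2)
    return polarity * (sharp - counter)


def make_ecg_trial(
    spec: EcgTrialSpec, stimulus_onset_s: float | None = None
) -> tuple[Waveform, dict]:
    """Simulate one ECG trial with planted beat times.

    Beat times realize the instantaneous rate
    ``r(t) = baseline_bpm + response_gain_bpm * g(t - onset)`` with ``g`` a
    causal rise/decay kernel: the k-th beat occurs when the integral of
    r(t)/60 crosses k.  Each beat is stamped with a fixed QRS template of
    the requested polarity; white noise is scaled relative to the QRS
    amplitude.  ``artifact_rate`` > 0 inserts movement bursts — spike
    triplets at < 62 ms spacing — whose times are recorded in the ground
    truth so trial-rejection logic can be tested against them.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    onset = spec.pre_s if stimulus_onset_s is None else stimulus_onset_s
    total_s = spec.pre_s + spec.post_s
    # integrate the rate on a fine grid and invert for beat times
    grid = np.arange(0.0, total_s, 1e-3)
    r = spec.baseline_bpm + spec.response_gain_bpm * _hr_kernel(
        grid - onset, spec.rise_s, spec.decay_s
    )
    cum_beats = np.concatenate([[0.0], np.cumsum(r[:-1] * np.diff(grid)) / 60.0])
    n_beats = int(np.floor(cum_beats[-1]))
    beat_times = np.interp(np.arange(1, n_beats + 1), cum_beats, grid)

    n = int(round(total_s * spec.rate_hz))
    x = np.zeros(n)
    template = _qrs_template(spec.rate_hz, spec.qrs_polarity)
    half = template.size // 2
    for bt in beat_times:
        i = int(round(bt * spec.rate_hz)) - half
        lo, hi = max(i, 0), min(i + template.size, n)
        x[lo:hi] += template[lo - i : hi - i]

    artifact_times = []
    n_art = rng.poisson(spec.artifact_rate)
    for _ in range(n_art):
        t0 = rng.uniform(0.5, total_s - 0.5)
        for j in range(3):  # triplet at 30 ms spacing -> intervals < 62 ms
            tj = t0 + 0.030 * j
            i = int(round(tj * spec.rate_hz)) - half
            lo, hi = max(i, 0), min(i + template.size, n)
            x[lo:hi] += 1.5 * template[lo - i : hi - i]
            artifact_times.append(tj)

    qrs_amp = np.max(np.abs(template))
    x += rng.normal(0.0, spec.noise_sd * qrs_amp, size=n)

    truth = {
        "beat_times_s": beat_times,
        "artifact_times_s": np.asarray(artifact_times),
        "stimulus_onset_s": onset,
        "baseline_bpm": spec.baseline_bpm,
        "response_gain_bpm": spec.response_gain_bpm,
        "rise_s": spec.rise_s,
        "decay_s": spec.decay_s,
    }
    return Waveform(x, spec.rate_hz), truth


# ---------------------------------------------------------------------------
# iEEG
# ---------------------------------------------------------------------------

def _powerlaw_noise(rng, n: int, alpha: float) -> np.ndarray:
    """1/f^alpha Gaussian noise, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** (-alpha / 2.0)
    x = np.fft.irfft(spec, n)
    return x / np.std(x)


def make_ieeg_trial(
    spec: IeegTrialSpec,
    stimulus: Waveform,
    onsets_s: np.ndarray,
    stimulus_am_rate_hz: float,
) -> Waveform:
    """Simulate an iEEG trace around a stimulus presentation.

    The trace is 1/f^alpha background noise over the whole trial; within
    each syllable window an evoked transient (damped deflection) plus a
    stimulus-locked sinusoid at ``stimulus_am_rate_hz`` scaled by
    ``ffr_gain`` is added.  The first onset is preceded by at least
    ``silent_baseline_s`` of stimulation-free baseline.
    """
    spec.validate()
    if stimulus_am_rate_hz >= spec.rate_hz / 2:
        raise ValueError("stimulus AM rate must lie below Nyquist")
    rng = np.random.default_rng(spec.seed)
    rate = spec.rate_hz
    onsets = np.asarray(onsets_s) + spec.silent_baseline_s
    total_s = spec.silent_baseline_s + stimulus.duration_s + spec.post_s
    n = int(round(total_s * rate))
    x = _powerlaw_noise(rng, n, spec.noise_exponent)

    # per-syllable window: mean syllable extent from consecutive onsets
    syl_dur_s = 0.006 if onsets.size < 2 else min(0.012, float(np.min(np.diff(onsets))) * 0.4)
    t_all = np.arange(n) / rate
    for o in onsets:
        i0 = int(round(o * rate))
        i1 = min(int(round((o + syl_dur_s) * rate)), n)
        if i1 <= i0:
            continue
        tau = t_all[i0:i1] - o
        evoked = spec.evoked_gain * np.exp(-tau / 0.004) * np.sin(2 * np.pi * 400.0 * tau)
        x[i0:i1] += evoked
        if spec.ffr_gain > 0 and stimulus_am_rate_hz > 0:
            # phase tied to global time: locked across syllables and trials
            x[i0:i1] += spec.ffr_gain * np.sin(
                2 * np.pi * stimulus_am_rate_hz * t_all[i0:i1]
            )
    return Waveform(x, rate)


# ---------------------------------------------------------------------------
# Ear canal / DPOAE
# ---------------------------------------------------------------------------

def make_ear_canal_epochs(spec: EarCanalSpec) -> np.ndarray:
    """Generate phase-locked two-tone ear-canal epochs.

    Each epoch contains the f1 and f2 primaries at their stated levels plus
    — when f2 lies at or above the cochlear cutoff — a 2f1-f2 cubic
    distortion product at ``dp_level_db``.  Deterministic components are
    identical (phase-locked) across epochs; white noise at ``noise_db``
    (RMS level in the same dB convention) is drawn independently per epoch,
    so coherent averaging suppresses it by sqrt(n_epochs).

    Amplitude convention: a component at L dB has peak amplitude
    10**(L/20) in arbitrary linear units, so spectrum levels read directly
    in dB.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.epoch_len) / spec.rate_hz

    def tone(freq, level_db):
        return 10 ** (level_db / 20.0) * np.sin(2 * np.pi * freq * t)

    base = tone(spec.f1_hz, spec.l1_db) + tone(spec.f2_hz, spec.l2_db)
    if spec.f2_hz >= spec.cochlear_cutoff_hz:
        base = base + tone(spec.dp_hz, spec.dp_level_db)

    noise_rms = 10 ** (spec.noise_db / 20.0)
    epochs = base[None, :] + rng.normal(
        0.0, noise_rms, size=(spec.n_epochs, spec.epoch_len)
    )
    return epochs
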