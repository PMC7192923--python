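"""Sampled-signal container shared by audio, ECG, iEEG and ear-canal data.

A :class:`Waveform` is the universal carrier of every trace the pipeline
touches: microphone audio at 192/300 kHz, ECG and iEEG voltage at 9.6 kHz,
and ear-canal pressure epochs.  Samples are dimensionless full-scale
amplitudes (|x| <= 1 for audio destined for 16-bit WAV); an optional
calibration constant maps full scale to sound pressure level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile


@dataclass
class Waveform:
    """A mono sampled signal.

    Parameters
    ----------
    samples
        1-D float array of amplitudes.
    rate_hz
        Sampling rate in Hz, > 0.
    calibration_db_fs
        dB SPL corresponding to a full-scale RMS sinusoid (i.e. a sine of
        peak amplitude 1).  ``None`` when the trace is uncalibrated.
    """

    samples: np.ndarray
    rate_hz: float
    calibration_db_fs: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform requires a 1-D (mono) sample array")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n) / self.rate_hz

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


def read_wav(path) -> Waveform:
    """Read a mono WAV file, scaling integer PCM to [-1, 1).

    Supported encodings: 16-bit and 32-bit integer PCM and 32/64-bit float.
    Stereo or multi-channel files are rejected — every signal in this
    pipeline is single-channel by construction.
    """
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV encoding {data.dtype}")
    return Waveform(samples, float(rate))


def write_wav(path, wave: Waveform, subtype: str = "float32"):
    """Write a Waveform as mono WAV (``float32`` or ``pcm16``)."""
    if subtype == "float32":
        wavfile.write(path, int(round(wave.rate_hz)), wave.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(wave.samples, -1.0, 32767.0 / 32768.0)
        wavfile.write(
            path, int(round(wave.rate_hz)), np.round(clipped * 32768.0).astype(np.int16)
        )
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")
    return path
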