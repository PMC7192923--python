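"""Per-syllable acoustic features.

Implements the feature battery used to characterize roughness-like
structure in vocalizations: the amplitude envelope (0.1 ms resolution), the
temporal modulation spectrum (TMS) with best modulation frequency (BMF) and
frequencies-of-interest (FOI, 1.15-2.45 kHz) area, the 200-Hz-resolution
power spectrum with peak frequency, spectral area and harmonic-to-noise
difference (HND), the spectral autocorrelogram with median inter-peak
distance (MIPD), and calibrated band sound-pressure levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .waveform import Waveform

FOI_LOW_HZ = 1150.0
FOI_HIGH_HZ = 2450.0


@dataclass
class EnvelopeSeries:
    """Amplitude envelope on a regular grid (default dt = 0.1 ms)."""

    values: np.ndarray
    dt_s: float = 0.0001

    @property
    def duration_s(self) -> float:
        return self.values.size * self.dt_s


@dataclass
class TMS:
    """Temporal modulation spectrum on a 0-4 kHz grid, unit total power."""

    freq_hz: np.ndarray
    power: np.ndarray
    bmf_hz: float | None
    foi_area: float
    degenerate: bool = False


@dataclass
class PowerSpectrum:
    """Magnitude spectrum interpolated to 200 Hz steps."""

    freq_hz: np.ndarray
    power: np.ndarray
    normalized: np.ndarray
    peak_frequency_hz: float
    spectral_area_khz: float
    hnd: float


@dataclass
class SpectralAutocorrelogram:
    """Autocorrelation of the spectrum over lags to +/-10 kHz."""

    lag_hz: np.ndarray
    corr: np.ndarray
    peak_lags_hz: np.ndarray
    mipd_hz: float | None


@dataclass
class BandLevel:
    band_hz: tuple
    level_db_spl: float


# ---------------------------------------------------------------------------

def amplitude_envelope(syllable: Waveform, dt_s: float = 0.0001) -> EnvelopeSeries:
    """Amplitude envelope: analytic-signal magnitude, low-passed, resampled.

    The magnitude of the analytic signal is low-pass filtered below
    1/(2*dt_s) (zero-phase 4th-order Butterworth) and linearly resampled to
    the ``dt_s`` grid.  This reproduces modulation extraction at 0.1 ms
    resolution: modulators up to 5 kHz survive, carrier-rate beating does
    not.
    """
    if syllable.n == 0:
        raise ValueError("empty input")
    if syllable.duration_s < 2 * dt_s:
        raise ValueError("syllable shorter than two envelope samples")
    x = syllable.samples
    if not np.any(x):
        n_out = int(np.floor(syllable.duration_s / dt_s))
        return EnvelopeSeries(np.zeros(n_out), dt_s)
    env = np.abs(signal.hilbert(x))
    cutoff = 1.0 / (2.0 * dt_s)
    nyq = syllable.rate_hz / 2.0
    if cutoff < nyq:
        sos = signal.butter(4, cutoff / nyq, output="sos")
        env = signal.sosfiltfilt(sos, env)
    t = np.arange(x.size) / syllable.rate_hz
    t_out = np.arange(0.0, syllable.duration_s - dt_s / 2, dt_s)
    values = np.interp(t_out, t, env)
    return EnvelopeSeries(np.maximum(values, 0.0), dt_s)


def temporal_modulation_spectrum(
    env: EnvelopeSeries,
    fmax_hz: float = 4000.0,
    pad_to_s: float = 1.0,
    foi: tuple = (FOI_LOW_HZ, FOI_HIGH_HZ),
) -> TMS:
    """TMS: magnitude-squared FFT of the mean-subtracted envelope.

    The envelope is zero-padded to ``pad_to_s`` so the modulation grid has
    a fixed 1 Hz resolution regardless of syllable duration; power is
    normalized to unit total over the 0-``fmax_hz`` grid.  ``bmf_hz`` is
    the argmax within the FOI band; ``foi_area`` the trapezoidal area of
    normalized power over the FOI.
    """
    if env.values.size == 0:
        raise ValueError("empty envelope")
    v = env.values - env.values.mean()
    n_pad = int(round(pad_to_s / env.dt_s))
    n_fft = max(n_pad, v.size)
    spec = np.fft.rfft(v, n_fft)
    freq = np.fft.rfftfreq(n_fft, env.dt_s)
    keep = freq <= fmax_hz
    freq = freq[keep]
    power = np.abs(spec[keep]) ** 2
    total = power.sum()
    if total <= 0:
        return TMS(freq, np.zeros_like(power), None, 0.0, degenerate=True)
    power = power / total
    in_foi = (freq >= foi[0]) & (freq <= foi[1])
    bmf = float(freq[in_foi][np.argmax(power[in_foi])])
    foi_area = float(np.trapezoid(power[in_foi], freq[in_foi]))
    return TMS(freq, power, bmf, foi_area)


def power_spectrum_200hz(syllable: Waveform, step_hz: float = 200.0) -> PowerSpectrum:
    """Magnitude spectrum linearly interpolated to a 200 Hz grid.

    The normalized copy is peak-scaled to 1; ``spectral_area_khz`` is the
    trapezoidal area under the normalized spectrum expressed in kHz of
    equivalent full-power bandwidth; ``hnd`` is the maximum absolute
    difference between the normalized spectrum and its 5-point moving
    average (shrinking windows at the edges).
    """
    if syllable.n == 0:
        raise ValueError("empty input")
    mag = np.abs(np.fft.rfft(syllable.samples))
    freq = np.fft.rfftfreq(syllable.n, 1.0 / syllable.rate_hz)
    grid = np.arange(0.0, syllable.rate_hz / 2 + step_hz / 2, step_hz)
    grid = grid[grid <= syllable.rate_hz / 2]
    power = np.interp(grid, freq, mag)
    peak = power.max()
    normalized = power / peak if peak > 0 else power
    peak_freq = float(grid[np.argmax(power)])
    area = float(np.trapezoid(normalized, grid)) / 1000.0
    smooth = _moving_average_shrinking(normalized, 5)
    hnd = float(np.max(np.abs(normalized - smooth)))
    return PowerSpectrum(grid, power, normalized, peak_freq, area, hnd)


def _moving_average_shrinking(x: np.ndarray, win: int) -> np.ndarray:
    """Centered moving average; the window shrinks at the edges."""
    half = win // 2
    c = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(x.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, x.size)
    return (c[hi] - c[lo]) / (hi - lo)


def spectral_autocorrelogram(
    spec: PowerSpectrum,
    prominence: float = 0.025,
    max_lag_hz: float = 10000.0,
    central: str = "median",
) -> SpectralAutocorrelogram:
    """Autocorrelation of the spectrum; regularity via inter-peak spacing.

    The normalized spectrum is autocorrelated directly (no mean removal —
    the positive baseline is what keeps noise fluctuations from producing
    spurious prominent maxima), scaled so lag 0 equals 1, and retained
    over lags to +/-``max_lag_hz``.  Local maxima are detected at the
    stated prominence; the lag-0 peak (the global maximum) always counts,
    so regular sidebands produce peaks at 0, d, 2d, ...  The MIPD is the
    median (or mean) of successive inter-peak distances; with fewer than
    two peaks in total — i.e. no prominent off-zero maximum, as for noisy
    spectra — it is undefined (``None``).
    """
    step = float(spec.freq_hz[1] - spec.freq_hz[0])
    v = spec.normalized
    n_lag = int(round(max_lag_hz / step))
    lags = np.arange(-n_lag, n_lag + 1) * step
    if not np.any(v):
        return SpectralAutocorrelogram(lags, np.zeros_like(lags, dtype=float), np.array([]), None)
    full = np.correlate(v, v, mode="full")
    mid = v.size - 1
    full = full / full[mid]
    lo = max(mid - n_lag, 0)
    hi = min(mid + n_lag + 1, full.size)
    corr = np.zeros(lags.size)
    corr[lo - (mid - n_lag) : hi - (mid - n_lag)] = full[lo:hi]

    pos = lags >= 0
    peaks, _ = signal.find_peaks(corr[pos], prominence=prominence)
    peak_lags = np.concatenate([[0.0], lags[pos][peaks]])  # lag 0 is the global max
    if peak_lags.size < 2:
        return SpectralAutocorrelogram(lags, corr, peak_lags, None)
    gaps = np.diff(peak_lags)
    mipd = float(np.median(gaps) if central == "median" else np.mean(gaps))
    return SpectralAutocorrelogram(lags, corr, peak_lags, mipd)


def band_spl(
    syllable: Waveform,
    band_hz: tuple,
    calibration_db_fs: float | None = None,
    order: int = 3,
) -> BandLevel:
    """Calibrated band level via 3rd-order Butterworth bandpass.

    ``level = 20*log10(rms_filtered / rms_ref) + 94`` where ``rms_ref`` is
    the RMS a 94 dB SPL calibrator tone would have under the supplied
    full-scale calibration.  Filtering is single-pass at the printed order
    (not zero-phase).
    """
    cal = calibration_db_fs if calibration_db_fs is not None else syllable.calibration_db_fs
    if cal is None:
        raise ValueError("band_spl requires calibration_db_fs")
    low, high = band_hz
    nyq = syllable.rate_hz / 2
    if not 0 < low < high < nyq:
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    sos = signal.butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")
    filtered = signal.sosfilt(sos, syllable.samples)
    rms = np.sqrt(np.mean(filtered**2))
    rms_ref = (1.0 / np.sqrt(2.0)) * 10 ** ((94.0 - cal) / 20.0)
    if rms <= 0:
        return BandLevel(band_hz, -np.inf)
    return BandLevel(band_hz, float(20 * np.log10(rms / rms_ref) + 94.0))


def carrier_modulator_ratio(peak_frequency_hz: float, bmf_hz: float | None) -> float | None:
    """Ratio of the strongest carrier frequency to the modulation rate.

    Undefined (``None``) when the BMF itself is undefined, so degenerate
    syllables are excluded from summaries rather than poisoning them.
    """
    if bmf_hz is None or bmf_hz <= 0:
        return None
    return float(peak_frequency_hz) / float(bmf_hz)


def syllable_features(
    syllable: Waveform,
    calibration_db_fs: float | None = None,
) -> dict:
    """Convenience bundle: all scalar features of one syllable."""
    env = amplitude_envelope(syllable)
    tms = temporal_modulation_spectrum(env)
    spec = power_spectrum_200hz(syllable)
    acorr = spectral_autocorrelogram(spec)
    out = {
        "duration_s": syllable.duration_s,
        "bmf_hz": tms.bmf_hz,
        "foi_area": tms.foi_area,
        "peak_frequency_hz": spec.peak_frequency_hz,
        "spectral_area_khz": spec.spectral_area_khz,
        "hnd": spec.hnd,
        "mipd_hz": acorr.mipd_hz,
        "carrier_modulator_ratio": carrier_modulator_ratio(
            spec.peak_frequency_hz, tms.bmf_hz
        ),
    }
    if calibration_db_fs is not None:
        out["band_spl_foi"] = band_spl(
            syllable, (FOI_LOW_HZ, FOI_HIGH_HZ), calibration_db_fs
        ).level_db_spl
        out["band_spl_20k"] = band_spl(
            syllable, (20000.0, 21300.0), calibration_db_fs
        ).level_db_spl
    return out
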