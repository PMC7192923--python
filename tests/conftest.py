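import numpy as np
import pytest

from vocalrough import SyllableSpec, make_syllable
from vocalrough.specfeat import amplitude_envelope, temporal_modulation_spectrum


@pytest.fixture(scope="session")
def rough_syllable_300k():
    """A fast-AM syllable at the analysis rate (300 kHz)."""
    spec = SyllableSpec(duration_s=0.008, am_rate_hz=1750, am_depth=0.9)
    wave, truth = make_syllable(spec, seed=1)
    return wave, truth


@pytest.fixture(scope="session")
def rough_syllable_192k():
    """A fast-AM syllable at the stimulus rate (192 kHz)."""
    spec = SyllableSpec(
        duration_s=0.006, am_rate_hz=1700, am_depth=0.9, rate_hz=192000.0
    )
    wave, truth = make_syllable(spec, seed=1)
    return wave, truth


def relative_foi_modulation_power(wave):
    """Envelope modulation power within 1.15-2.45 kHz, gain-invariant.

    The envelope is normalized by its mean (so the measure reflects
    modulation, not level) and band-passed over the frequencies of
    interest; the mean square of the result is returned.
    """
    from scipy import signal

    env = amplitude_envelope(wave).values
    rel = env / env.mean() - 1.0
    sos = signal.butter(4, [1150 / 5000, 2450 / 5000], btype="band", output="sos")
    return float(np.mean(signal.sosfiltfilt(sos, rel) ** 2))
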