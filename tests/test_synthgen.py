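"""Generator contracts: planted structure must be present and recoverable."""

import numpy as np
import pytest

from vocalrough import (
    CorpusSpec,
    EarCanalSpec,
    EcgTrialSpec,
    IeegTrialSpec,
    SequenceLayout,
    SyllableSpec,
    Waveform,
    make_am_tone,
    make_distress_corpus,
    make_ear_canal_epochs,
    make_ecg_trial,
    make_ieeg_trial,
    make_stimulus_sequence,
    make_syllable,
)
from vocalrough.specfeat import amplitude_envelope


def modulation_depth(env_values, trim):
    v = env_values[trim:-trim]
    return (v.max() - v.min()) / (v.max() + v.min())


class TestMakeSyllable:
    def test_unmodulated_envelope_flat(self):
        wave, _ = make_syllable(SyllableSpec(am_rate_hz=0.0), seed=0)
        env = amplitude_envelope(wave).values
        interior = env[8:-8]  # clear of the 0.3 ms ramps
        assert np.ptp(interior) / interior.mean() < 0.02

    def test_am_depth_recovered_from_envelope(self):
        spec = SyllableSpec(duration_s=0.008, am_rate_hz=1700, am_depth=0.9)
        wave, truth = make_syllable(spec, seed=1)
        depth = modulation_depth(amplitude_envelope(wave).values, 8)
        assert truth["am_rate_hz"] == 1700.0
        assert abs(depth - 0.9) < 0.05 * 0.9

    def test_sfm_ridge_oscillates(self):
        """The SFM variant's spectrogram ridge follows a sinusoidal track."""
        from vocalrough.modspec import ridge_trajectory, stft_fixed

        spec = SyllableSpec(
            duration_s=0.012, am_rate_hz=0.0, fm_variant="SFM", rate_hz=192000.0
        )
        wave, truth = make_syllable(spec, seed=1)
        assert truth["fm_variant"] == "SFM"
        ridge = ridge_trajectory(stft_fixed(wave))
        t = np.arange(ridge.size) / 192000.0
        expected = np.sin(2 * np.pi * spec.sfm_rate_hz * t)
        r = np.corrcoef(ridge - ridge.mean(), expected)[0, 1]
        assert abs(r) > 0.8

    def test_harmonic_above_nyquist_rejected(self):
        spec = SyllableSpec(n_harmonics=6)  # 6 x 28 kHz > 150 kHz
        with pytest.raises(ValueError, match="Nyquist"):
            make_syllable(spec, seed=0)

    def test_bit_reproducible_under_seed(self):
        spec = SyllableSpec()
        a, _ = make_syllable(spec, seed=7)
        b, _ = make_syllable(spec, seed=7)
        assert np.array_equal(a.samples, b.samples)


class TestAmTone:
    def test_sidebands_at_carrier_plus_minus_rate(self):
        tone = make_am_tone(20000, 1700, 0.2, 192000)
        mag = np.abs(np.fft.rfft(tone.samples))
        freq = np.fft.rfftfreq(tone.n, 1 / 192000)
        for f in (18300.0, 20000.0, 21700.0):
            i = np.argmin(np.abs(freq - f))
            window = mag[max(i - 300, 0) : i + 300]
            assert mag[i] > 10 * np.median(window)

    def test_zero_rate_gives_pure_tone(self):
        tone = make_am_tone(20000, 0, 0.2, 192000)
        mag = np.abs(np.fft.rfft(tone.samples))
        freq = np.fft.rfftfreq(tone.n, 1 / 192000)
        assert abs(freq[np.argmax(mag)] - 20000) < 10

    def test_carrier_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            make_am_tone(100000, 1700, 0.1, 192000)


class TestCorpus:
    def test_realized_fraction_near_target(self):
        # ~5000 syllables: binomial sd ~0.007, so +/-0.02 is a 3-sigma band
        spec = CorpusSpec(n_sequences=80, fam_fraction=0.477, seed=1)
        _, truth = make_distress_corpus(spec)
        assert len(truth) > 4000
        assert abs((truth.label == "fAMV").mean() - 0.477) < 0.02

    def test_zero_fraction_all_slow(self):
        _, truth = make_distress_corpus(CorpusSpec(n_sequences=5, fam_fraction=0.0, seed=2))
        assert (truth.label == "sAMV").all()

    def test_position_bias_shifts_fast_left(self):
        _, truth = make_distress_corpus(
            CorpusSpec(n_sequences=40, position_bias=1.0, seed=3)
        )
        fast_pos = truth[truth.label == "fAMV"].norm_position
        assert fast_pos.median() < 0.5

    def test_empty_corpus_warns(self):
        with pytest.warns(UserWarning):
            seqs, truth = make_distress_corpus(CorpusSpec(n_sequences=0))
        assert seqs == [] and len(truth) == 0

    def test_reproducible(self):
        a, ta = make_distress_corpus(CorpusSpec(n_sequences=3, seed=11))
        b, tb = make_distress_corpus(CorpusSpec(n_sequences=3, seed=11))
        assert all(np.array_equal(x.samples, y.samples) for x, y in zip(a, b))
        assert ta.equals(tb)


class TestStimulusSequence:
    def test_default_layout_66_onsets(self, rough_syllable_300k):
        wave, _ = rough_syllable_300k
        _, onsets = make_stimulus_sequence(wave)
        assert len(onsets) == 66

    def test_single_copy_is_faded_syllable(self, rough_syllable_300k):
        wave, _ = rough_syllable_300k
        seq, onsets = make_stimulus_sequence(
            wave, SequenceLayout(n_bouts=1, syllables_per_bout=1)
        )
        assert len(onsets) == 1 and onsets[0] == 0.0
        assert seq.n == wave.n
        # interior untouched by the 0.2 ms fades
        n_fade = int(0.0002 * wave.rate_hz)
        assert np.allclose(seq.samples[n_fade:-n_fade], wave.samples[n_fade:-n_fade])

    def test_total_duration_from_silent_gap_arithmetic(self):
        # 11 bouts x (6 x 5 ms + 5 x 14 ms) + 10 x 80 ms = 1900 ms
        syl, _ = make_syllable(SyllableSpec(duration_s=0.005), seed=1)
        seq, _ = make_stimulus_sequence(syl)
        assert seq.n == int(round(1.9 * syl.rate_hz))


class TestEcgTrial:
    def test_constant_rate_without_response(self):
        _, truth = make_ecg_trial(EcgTrialSpec(response_gain_bpm=0.0, seed=0))
        intervals = np.diff(truth["beat_times_s"])
        assert np.allclose(intervals, 60.0 / 480.0, atol=1e-4)

    def test_response_shortens_post_onset_intervals(self):
        _, truth = make_ecg_trial(EcgTrialSpec(response_gain_bpm=100.0, seed=0))
        bt = truth["beat_times_s"]
        onset = truth["stimulus_onset_s"]
        pre = np.diff(bt[bt < onset])
        post = np.diff(bt[bt > onset])
        assert post.min() < pre.min()

    def test_artifacts_plant_sub_62ms_intervals(self):
        _, truth = make_ecg_trial(EcgTrialSpec(artifact_rate=3.0, seed=1))
        events = np.sort(np.concatenate(
            [truth["beat_times_s"], truth["artifact_times_s"]]
        ))
        assert truth["artifact_times_s"].size > 0
        assert np.min(np.diff(events)) < 0.062


class TestIeegTrial:
    @staticmethod
    def _stimulus():
        syl, _ = make_syllable(
            SyllableSpec(duration_s=0.005, am_rate_hz=1700, am_depth=0.9,
                         rate_hz=192000.0), seed=1,
        )
        return make_stimulus_sequence(syl)

    def test_silent_baseline_honored(self):
        seq, onsets = self._stimulus()
        spec = IeegTrialSpec(ffr_gain=0.5, seed=0)
        trace = make_ieeg_trial(spec, seq, onsets, 1700.0)
        # first 1.4 s must be statistically identical to pure background
        base = trace.samples[: int(1.4 * spec.rate_hz)]
        rest_rms = np.sqrt(np.mean(trace.samples**2))
        assert np.sqrt(np.mean(base**2)) < 1.5 * rest_rms

    def test_planted_ffr_adds_narrowband_power(self):
        seq, onsets = self._stimulus()
        def band_power(gain, seed=3):
            tr = make_ieeg_trial(IeegTrialSpec(ffr_gain=gain, seed=seed), seq, onsets, 1700.0)
            mag = np.abs(np.fft.rfft(tr.samples))
            freq = np.fft.rfftfreq(tr.n, 1 / tr.rate_hz)
            sel = (freq >= 1650) & (freq <= 1750)
            return float(np.mean(mag[sel] ** 2))
        assert band_power(0.5) > 2 * band_power(0.0)

    def test_am_rate_above_nyquist_rejected(self):
        seq, onsets = self._stimulus()
        with pytest.raises(ValueError):
            make_ieeg_trial(IeegTrialSpec(), seq, onsets, 6000.0)

    def test_baseline_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            IeegTrialSpec(silent_baseline_s=1.0).validate()


class TestEarCanal:
    def test_planted_dp_line_present(self):
        spec = EarCanalSpec(f2_hz=18000.0, dp_level_db=25.0, seed=1)
        epochs = make_ear_canal_epochs(spec)
        avg = epochs.mean(axis=0)
        mag = np.abs(np.fft.rfft(avg * np.hanning(avg.size)))
        freq = np.fft.rfftfreq(avg.size, 1 / spec.rate_hz)
        i = np.argmin(np.abs(freq - 10800.0))
        neighborhood = mag[i - 80 : i + 80]
        assert mag[i - 3 : i + 4].max() > 10 * np.median(neighborhood)

    def test_no_dp_below_cochlear_cutoff(self):
        spec = EarCanalSpec(f2_hz=1800.0, dp_level_db=25.0, noise_db=-np.inf, seed=1)
        epochs = make_ear_canal_epochs(spec)
        avg = epochs.mean(axis=0)
        mag = np.abs(np.fft.rfft(avg * np.hanning(avg.size)))
        freq = np.fft.rfftfreq(avg.size, 1 / spec.rate_hz)
        dp = 2 * spec.f1_hz - spec.f2_hz
        i = np.argmin(np.abs(freq - dp))
        # nothing planted: at most numerical leakage from the primaries
        assert mag[i] < 1e-3 * mag.max()

    def test_zero_noise_epochs_identical(self):
        spec = EarCanalSpec(noise_db=-np.inf, seed=1)
        epochs = make_ear_canal_epochs(spec)
        assert np.allclose(epochs, epochs[0][None, :])

    def test_ratio_invariant_enforced(self):
        with pytest.raises(ValueError):
            EarCanalSpec(f2_hz=18000.0, f1_hz=15000.0).validate()
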