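"""ECG, iEEG and DPOAE response quantification."""

import numpy as np
import pytest

from vocalrough import (
    EarCanalSpec,
    EcgTrialSpec,
    IeegTrialSpec,
    SyllableSpec,
    Waveform,
    detect_qrs,
    dp_analysis,
    dpgram,
    evoked_average,
    hr_condition_summary,
    hr_curve,
    make_ear_canal_epochs,
    make_ecg_trial,
    make_ieeg_trial,
    make_stimulus_sequence,
    make_syllable,
    multitaper_ffr,
)
from vocalrough.physio import QRSSeries, instantaneous_hr, multitaper_spectrogram, baseline_correct


class TestQRSDetection:
    def test_planted_beats_recovered_at_snr_10(self):
        for seed in range(6):
            ecg, truth = make_ecg_trial(
                EcgTrialSpec(baseline_bpm=600.0, noise_sd=0.1, seed=seed)
            )
            qrs = detect_qrs(ecg)
            bt = truth["beat_times_s"]
            assert len(qrs.times_s) == len(bt), seed
            assert np.max(np.abs(qrs.times_s - bt)) < 0.002

    def test_flat_trace_no_events(self):
        assert detect_qrs(Waveform(np.zeros(9600), 9600.0)).times_s.size == 0

    def test_small_spikes_below_threshold_ignored(self):
        """QRS-shaped spikelets at 1.5x the noise scale do not qualify as
        events; only the true beats are returned."""
        from vocalrough.synthgen import _qrs_template

        ecg, truth = make_ecg_trial(
            EcgTrialSpec(baseline_bpm=480.0, noise_sd=0.1, seed=5)
        )
        x = ecg.samples.copy()
        template = _qrs_template(ecg.rate_hz, -1) * 0.15  # 1.5 x noise SD
        spike_times = truth["beat_times_s"][:-1] + 0.06  # between beats
        for t in spike_times:
            i = int(t * ecg.rate_hz)
            x[i : i + template.size] += template
        qrs = detect_qrs(Waveform(x, ecg.rate_hz))
        assert len(qrs.times_s) == len(truth["beat_times_s"])
        assert np.max(np.abs(qrs.times_s - truth["beat_times_s"])) < 0.002


class TestHRCurve:
    def test_instantaneous_hr_formula_exact(self):
        intervals = np.array([0.05, 0.0625, 0.1, 0.125, 0.2])
        times = np.concatenate([[0.0], np.cumsum(intervals)])
        t, hr = instantaneous_hr(QRSSeries(times, 0.0, 1))
        assert np.allclose(hr, 60.0 / intervals)

    def test_62ms_interval_invalidates_trial(self):
        # 62 ms -> 967.7 bpm, above the 960 bpm movement-artifact bound
        times = np.concatenate([np.arange(0.0, 5.0, 0.125),
                                [5.031, 5.093],
                                np.arange(5.25, 15.0, 0.125)])
        curve = hr_curve(QRSSeries(np.unique(times), 0.0, 1), 5.0)
        assert not curve.valid

    def test_validity_monotone_under_added_short_interval(self):
        base = np.arange(0.0, 15.0, 0.125)
        assert hr_curve(QRSSeries(base, 0.0, 1), 5.0).valid
        spoiled = np.sort(np.append(base, 7.03))  # 30 ms to its neighbor
        assert not hr_curve(QRSSeries(spoiled, 0.0, 1), 5.0).valid

    def test_constant_train_zero_area(self):
        times = np.arange(0.0, 15.0, 0.1)
        curve = hr_curve(QRSSeries(times, 0.0, 1), 5.0)
        assert curve.valid
        assert abs(curve.response_area) < 2.0

    def test_planted_response_area_recovered(self):
        ecg, truth = make_ecg_trial(
            EcgTrialSpec(response_gain_bpm=80.0, noise_sd=0.05, seed=3)
        )
        curve = hr_curve(detect_qrs(ecg), truth["stimulus_onset_s"])
        t = np.linspace(0, 10, 4001)
        g = (1 - np.exp(-t / truth["rise_s"])) * np.exp(-t / truth["decay_s"])
        planted = truth["response_gain_bpm"] * np.trapezoid(g / g.max(), t)
        assert curve.valid
        assert abs(curve.response_area - planted) < 0.15 * planted


class TestConditionSummary:
    @staticmethod
    def _cohort(n_animals, gain_a, gain_b, seed0, n_trials=2):
        trials = {}
        rng = np.random.default_rng(seed0)
        for a in range(n_animals):
            by_cond = {}
            for cond, gain in (("A", gain_a), ("B", gain_b)):
                curves = []
                for _ in range(n_trials):
                    ecg, truth = make_ecg_trial(EcgTrialSpec(
                        baseline_bpm=480.0 + 10 * a, response_gain_bpm=gain,
                        noise_sd=0.05, seed=int(rng.integers(2**31)),
                    ))
                    curves.append(hr_curve(detect_qrs(ecg), truth["stimulus_onset_s"]))
                by_cond[cond] = curves
            trials[f"bat{a}"] = by_cond
        return trials

    def test_planted_condition_difference_detected(self):
        summary = hr_condition_summary(self._cohort(12, 80.0, 30.0, 1))
        diffs = [r["mean_area"]["A"] - r["mean_area"]["B"]
                 for r in summary["per_animal"].values()]
        assert all(d > 0 for d in diffs)
        assert summary["paired_p"] < 0.01

    def test_z_scores_sum_to_zero_within_animal(self):
        summary = hr_condition_summary(self._cohort(4, 60.0, 60.0, 2))
        for rec in summary["per_animal"].values():
            assert abs(sum(rec["z_area"].values())) < 1e-9

    def test_single_animal_no_pvalue_but_areas_reported(self):
        summary = hr_condition_summary(self._cohort(1, 80.0, 30.0, 3))
        assert np.isnan(summary["paired_p"])
        assert len(summary["per_animal"]) == 1


@pytest.fixture(scope="module")
def ieeg_stimulus():
    syl, _ = make_syllable(
        SyllableSpec(duration_s=0.005, am_rate_hz=1700, am_depth=0.9,
                     rate_hz=192000.0), seed=1,
    )
    return make_stimulus_sequence(syl)


class TestFFR:
    def test_planted_ffr_beats_control_every_seed(self, ieeg_stimulus):
        seq, onsets = ieeg_stimulus
        for seed in range(20):
            powers = {}
            for gain in (0.5, 0.0):
                spec = IeegTrialSpec(ffr_gain=gain, seed=seed)
                trace = make_ieeg_trial(spec, seq, onsets, 1700.0)
                _, powers[gain] = multitaper_ffr(trace, onsets + spec.silent_baseline_s)
            assert powers[0.5] > powers[0.0], seed

    def test_baseline_correction_centers_silence(self):
        rng = np.random.default_rng(0)
        trace = Waveform(rng.standard_normal(4 * 9600), 9600.0)
        spg = multitaper_spectrogram(trace)
        corrected = baseline_correct(spg, (0.1, 1.4))
        sel = (spg.time_s >= 0.1) & (spg.time_s <= 1.4)
        resid = corrected.corrected[:, sel].mean(axis=1)
        se = corrected.corrected[:, sel].std(axis=1) / np.sqrt(sel.sum())
        assert np.all(np.abs(resid) <= 3 * se + 1e-12)

    def test_band_edges_honored(self, ieeg_stimulus):
        """Power planted just outside 1.6-2 kHz does not raise band power."""
        seq, onsets = ieeg_stimulus
        base = IeegTrialSpec(ffr_gain=0.0, seed=4)
        control = make_ieeg_trial(base, seq, onsets, 1700.0)
        outside = make_ieeg_trial(IeegTrialSpec(ffr_gain=0.8, seed=4), seq, onsets, 2500.0)
        _, p_control = multitaper_ffr(control, onsets + 1.5)
        _, p_outside = multitaper_ffr(outside, onsets + 1.5)
        # 2.5 kHz is ~3 multitaper bandwidths above the band edge
        assert p_outside < p_control + 5 * abs(p_control)

    def test_insufficient_baseline_rejected(self, ieeg_stimulus):
        seq, onsets = ieeg_stimulus
        trace = make_ieeg_trial(IeegTrialSpec(seed=0), seq, onsets, 1700.0)
        with pytest.raises(ValueError, match="baseline"):
            multitaper_ffr(trace, onsets + 0.5)


class TestEvokedAverage:
    def test_single_window_is_identity(self):
        rng = np.random.default_rng(0)
        trace = Waveform(rng.standard_normal(9600), 9600.0)
        avg = evoked_average(trace, [0.1], window_s=0.02)
        i0 = int(0.1 * 9600)
        assert np.allclose(avg.samples, trace.samples[i0 : i0 + avg.n])

    def test_residual_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(1)
        rate = 9600.0
        n_win = int(0.02 * rate)
        t = np.arange(n_win) / rate
        template = np.sin(2 * np.pi * 1700 * t) * np.exp(-t / 0.01)
        errs = []
        for n in (10, 100, 1000):
            x = rng.normal(0, 1.0, n_win * (n + 2))
            onsets = (np.arange(n) * n_win + n_win // 2) / rate
            for o in onsets:
                i = int(o * rate)
                x[i : i + n_win] += template
            avg = evoked_average(Waveform(x, rate), onsets)
            errs.append(np.sqrt(np.mean((avg.samples - template) ** 2)))
        for a, b in zip(errs, errs[1:]):
            assert 2.0 < a / b < 4.8  # ~sqrt(10)

    def test_ffr_visible_in_average_spectrum(self, ieeg_stimulus):
        seq, onsets = ieeg_stimulus
        spec = IeegTrialSpec(ffr_gain=1.0, evoked_gain=0.3, seed=2)
        trace = make_ieeg_trial(spec, seq, onsets, 1700.0)
        avg = evoked_average(trace, onsets + spec.silent_baseline_s, window_s=0.006)
        mag = np.abs(np.fft.rfft(avg.samples))
        freq = np.fft.rfftfreq(avg.n, 1 / avg.rate_hz)
        sel = (freq >= 1000) & (freq <= 2500)
        assert abs(freq[sel][np.argmax(mag[sel])] - 1700.0) <= 200.0

    def test_overrunning_window_dropped_with_warning(self):
        trace = Waveform(np.zeros(960), 9600.0)
        with pytest.warns(UserWarning):
            avg = evoked_average(trace, [0.0, 0.095], window_s=0.02)
        assert avg.n == int(0.02 * 9600)


class TestDPOAE:
    def test_planted_dp_recovered_within_1db(self):
        spec = EarCanalSpec(f2_hz=18000.0, dp_level_db=25.0, seed=1)
        res = dp_analysis(make_ear_canal_epochs(spec), spec)
        assert abs(res.dp_amplitude_db - 25.0) < 1.0
        assert res.detected
        assert res.dp_amplitude_db - res.noise_floor_db > 20.0

    def test_no_dp_below_cutoff_sits_in_noise(self):
        spec = EarCanalSpec(f2_hz=1800.0, dp_level_db=25.0, seed=1)
        res = dp_analysis(make_ear_canal_epochs(spec), spec)
        assert abs(res.dp_amplitude_db - res.noise_floor_db) < 3.0
        assert not res.detected

    def test_coherent_averaging_drops_floor_20db(self):
        # quiet primaries so the floor is noise- and not leakage-limited
        floors = {}
        for n in (1, 100):
            spec = EarCanalSpec(f2_hz=1800.0, l1_db=-100.0, l2_db=-100.0,
                                n_epochs=n, seed=2)
            res = dp_analysis(make_ear_canal_epochs(spec), spec)
            floors[n] = res.noise_floor_db
        assert abs((floors[1] - floors[100]) - 20.0) <= 3.0

    def test_dpgram_detection_tracks_cochlear_cutoff(self):
        base = EarCanalSpec(seed=3)
        grid = np.arange(1000.0, 25001.0, 1000.0)
        results = dpgram(grid, base, seed=3)
        for f2, res in results:
            assert res.detected == (f2 >= base.cochlear_cutoff_hz), f2

    def test_nonpositive_dp_frequency_rejected(self):
        spec = EarCanalSpec(f2_hz=18000.0)
        spec.f1_hz = 8000.0  # 2f1 - f2 < 0
        with pytest.raises(ValueError):
            dp_analysis(np.zeros((2, 8192)), spec)
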