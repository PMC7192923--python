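"""Desk-scale orchestration of the full study on synthetic data.

``run_acoustics`` reproduces the corpus analysis: generate distress and
social corpora with planted fast-AM fractions, segment, extract features,
classify, and test the sequence-position skew, reporting ground-truth
recovery alongside the group statistics.  ``run_physiology`` reproduces
the stimulation experiments: build modulated and MPS-demodulated stimulus
sequences for the three syllable variants, simulate ECG and iEEG cohorts,
and quantify heart-rate response areas, FFR band powers and DPgrams.

Problem sizes default to desk scale (a few thousand syllables, a dozen
synthetic animals); every stage is deterministic under the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import audioseg, effectstats, modspec, physio, roughclass, specfeat, synthgen
from .synthgen import (
    CorpusSpec, EcgTrialSpec, IeegTrialSpec, EarCanalSpec,
    SequenceLayout, SyllableSpec,
)
from .waveform import Waveform

SYLLABLE_VARIANTS = (synthgen.FM, synthgen.QCF_FM, synthgen.SFM)


@dataclass
class RunConfig:
    """Every stage's parameters, serialized with the report."""

    seed: int = 1
    # acoustics
    n_distress_sequences: int = 30
    n_social_sequences: int = 15
    distress_fam_fraction: float = 0.477
    social_fam_fraction: float = 0.063
    position_bias: float = 0.3
    syllables_median: float = 60.0
    # physiology
    stimulus_duration_s: float = 0.020
    stimulus_am_rate_hz: float = 1700.0
    stimulus_am_depth: float = 0.9
    variants: tuple = SYLLABLE_VARIANTS
    n_ecg_animals: int = 12
    n_ecg_trials: int = 10
    ecg_artifact_rate: float = 0.0
    hr_gain_modulated_bpm: float = 80.0
    hr_gain_demodulated_bpm: float = 40.0
    n_ieeg_animals: int = 11
    ffr_gain_modulated: float = 0.5
    ffr_gain_demodulated: float = 0.0
    dpgram_f2_coarse_hz: tuple = tuple(np.arange(1000.0, 25001.0, 1000.0))
    dpgram_f2_fine_hz: tuple = tuple(np.arange(1000.0, 3201.0, 200.0))


def artifact_rate_for_fraction(fraction: float) -> float:
    """Poisson burst rate yielding the requested rejected-trial fraction."""
    return float(-np.log(1.0 - fraction))


# ---------------------------------------------------------------------------
# Acoustics
# ---------------------------------------------------------------------------

def _corpus_stage(corpus_spec: CorpusSpec, model) -> dict:
    """Segment one corpus, extract features, classify, compare to truth."""
    sequences, truth = synthgen.make_distress_corpus(corpus_spec)
    rows = []
    labels_by_seq = []
    for i, seq in enumerate(sequences):
        segs = audioseg.segment_syllables(seq, source=f"seq{i:03d}")
        sub = truth[truth.sequence == i].reset_index(drop=True)
        seq_labels = []
        for j, seg in enumerate(segs):
            feats = specfeat.syllable_features(seg.waveform())
            tms = specfeat.temporal_modulation_spectrum(
                specfeat.amplitude_envelope(seg.waveform())
            )
            fv = roughclass.tms_feature_vector(tms)
            label = model.svc.predict(fv[None, :])[0]
            seq_labels.append(label)
            row = {"sequence": i, "index": j, "start_s": seg.start_s,
                   "label": label, **feats}
            if j < len(sub):
                row["true_label"] = sub.label[j]
                row["true_am_rate_hz"] = sub.am_rate_hz[j]
            rows.append(row)
        labels_by_seq.append(np.asarray(seq_labels))
    table = pd.DataFrame(rows)
    n_true = len(truth)
    agreement = float((table.label == table.true_label).mean()) if len(table) else float("nan")
    return {
        "table": table,
        "labels_by_seq": labels_by_seq,
        "n_planted": n_true,
        "n_segmented": int(len(table)),
        "planted_fast_fraction": float((truth.label == roughclass.FAST).mean()) if n_true else float("nan"),
        "recovered_fast_fraction": float((table.label == roughclass.FAST).mean()) if len(table) else float("nan"),
        "label_agreement": agreement,
    }


def run_acoustics(config: RunConfig) -> dict:
    """Corpus analysis: segmentation, classification, position skew, stats."""
    rng = np.random.default_rng(config.seed)
    feats, labels = roughclass.make_training_features(seed=int(rng.integers(2**31)))
    model = roughclass.train_classifier(feats, labels, seed=config.seed)

    distress = _corpus_stage(
        CorpusSpec(
            n_sequences=config.n_distress_sequences,
            syllables_median=config.syllables_median,
            fam_fraction=config.distress_fam_fraction,
            position_bias=config.position_bias,
            seed=int(rng.integers(2**31)),
        ),
        model,
    )
    social = _corpus_stage(
        CorpusSpec(
            n_sequences=config.n_social_sequences,
            syllables_median=config.syllables_median,
            fam_fraction=config.social_fam_fraction,
            position_bias=0.0,
            seed=int(rng.integers(2**31)),
        ),
        model,
    )

    pos = roughclass.position_analysis(
        distress["labels_by_seq"], seed=int(rng.integers(2**31))
    )

    table = distress["table"]
    fast = table[table.label == roughclass.FAST]
    slow = table[table.label == roughclass.SLOW]
    group_stats = {}
    for feat in ("foi_area", "peak_frequency_hz", "spectral_area_khz", "hnd"):
        rep = effectstats.compare_groups(
            fast[feat].dropna(), slow[feat].dropna(), paired=False
        )
        group_stats[feat] = {"cliffs_delta": rep.d, "bin": rep.bin, "ranksum_p": rep.p}

    return {
        "cv_error": model.cv_error,
        "distress": {k: v for k, v in distress.items() if k not in ("table", "labels_by_seq")},
        "social": {k: v for k, v in social.items() if k not in ("table", "labels_by_seq")},
        "position": {
            "median_observed": float(np.median(pos.observed_positions)),
            "ks_statistic": pos.ks_statistic,
            "ks_p": pos.ks_p,
            "halves_p": pos.halves_p,
        },
        "group_stats": group_stats,
        "_tables": {"distress": distress["table"], "social": social["table"]},
    }


# ---------------------------------------------------------------------------
# Physiology
# ---------------------------------------------------------------------------

def build_stimuli(config: RunConfig) -> dict:
    """The six stimulus sequences: three variants x natural/demodulated.

    Each demodulated syllable must pass the 2% synthesis-error gate before
    being admitted as a stimulus.
    """
    stimuli = {}
    for variant in config.variants:
        spec = SyllableSpec(
            duration_s=config.stimulus_duration_s,
            am_rate_hz=config.stimulus_am_rate_hz,
            am_depth=config.stimulus_am_depth,
            fm_variant=variant,
            rate_hz=192000.0,
        )
        syl, _ = synthgen.make_syllable(spec, seed=config.seed)
        demod, report = modspec.demodulate(syl)
        if report.synthesis_error_pct > 2.0:
            raise RuntimeError(
                f"{variant}: synthesis error {report.synthesis_error_pct:.2f}% "
                "exceeds the 2% stimulus gate"
            )
        seq_nat, onsets = synthgen.make_stimulus_sequence(syl, SequenceLayout())
        seq_dem, _ = synthgen.make_stimulus_sequence(demod, SequenceLayout())
        stimuli[variant] = {
            "natural": (seq_nat, onsets),
            "demodulated": (seq_dem, onsets),
            "synthesis_error_pct": report.synthesis_error_pct,
        }
    return stimuli


def run_physiology(config: RunConfig, stimuli: dict | None = None) -> dict:
    """Stimulation experiments: HR responses, FFR band power, DPgrams."""
    rng = np.random.default_rng(config.seed + 1)
    stimuli = stimuli or build_stimuli(config)

    # --- ECG cohort -------------------------------------------------------
    hr_results = {}
    n_rejected = 0
    n_with_artifacts = 0
    n_trials_total = 0
    for variant in config.variants:
        trials = {}
        for a in range(config.n_ecg_animals):
            by_cond = {}
            for cond, gain in (
                ("natural", config.hr_gain_modulated_bpm),
                ("demodulated", config.hr_gain_demodulated_bpm),
            ):
                curves = []
                for _ in range(config.n_ecg_trials):
                    spec = EcgTrialSpec(
                        baseline_bpm=480.0 + 5.0 * a,
                        response_gain_bpm=gain,
                        noise_sd=0.05,
                        artifact_rate=config.ecg_artifact_rate,
                        seed=int(rng.integers(2**31)),
                    )
                    ecg, truth = synthgen.make_ecg_trial(spec)
                    curve = physio.hr_curve(
                        physio.detect_qrs(ecg), truth["stimulus_onset_s"]
                    )
                    curves.append(curve)
                    n_trials_total += 1
                    n_rejected += not curve.valid
                    n_with_artifacts += truth["artifact_times_s"].size > 0
                by_cond[cond] = curves
            trials[f"animal{a:02d}"] = by_cond
        summary = physio.hr_condition_summary(trials)
        mean_areas = {
            cond: float(np.nanmean([
                rec["mean_area"][cond] for rec in summary["per_animal"].values()
            ]))
            for cond in ("natural", "demodulated")
        }
        hr_results[variant] = {
            "mean_area_natural": mean_areas["natural"],
            "mean_area_demodulated": mean_areas["demodulated"],
            "signrank_p": summary["paired_p"],
            "n_animals": config.n_ecg_animals,
        }

    # --- iEEG cohort ------------------------------------------------------
    ffr_results = {}
    for variant in config.variants:
        diffs = []
        for a in range(config.n_ieeg_animals):
            powers = {}
            for cond, gain in (
                ("natural", config.ffr_gain_modulated),
                ("demodulated", config.ffr_gain_demodulated),
            ):
                seq, onsets = stimuli[variant][cond]
                spec = IeegTrialSpec(ffr_gain=gain, seed=int(rng.integers(2**31)))
                trace = synthgen.make_ieeg_trial(
                    spec, seq, onsets, config.stimulus_am_rate_hz
                )
                _, power = physio.multitaper_ffr(
                    trace, np.asarray(onsets) + spec.silent_baseline_s
                )
                powers[cond] = power
            diffs.append(powers["natural"] - powers["demodulated"])
        diffs = np.asarray(diffs)
        p = float(
            effectstats.paired_and_unpaired_tests(diffs, np.zeros_like(diffs), paired=True)
        ) if np.any(diffs != 0) else float("nan")
        ffr_results[variant] = {
            "n_animals_natural_greater": int(np.sum(diffs > 0)),
            "n_animals": config.n_ieeg_animals,
            "signrank_p": p,
        }

    # --- DPgrams ----------------------------------------------------------
    def dpgram_summary(grid):
        base = EarCanalSpec(seed=int(rng.integers(2**31)))
        out = physio.dpgram(np.asarray(grid), base, seed=int(rng.integers(2**31)))
        return [
            {"f2_hz": f2, "dp_db": r.dp_amplitude_db,
             "floor_db": r.noise_floor_db, "detected": bool(r.detected)}
            for f2, r in out
        ]

    return {
        "synthesis_errors_pct": {
            v: stimuli[v]["synthesis_error_pct"] for v in config.variants
        },
        "heart_rate": hr_results,
        "ffr": ffr_results,
        "ecg_rejected_fraction": n_rejected / n_trials_total if n_trials_total else float("nan"),
        "ecg_planted_artifact_fraction": n_with_artifacts / n_trials_total if n_trials_total else float("nan"),
        "dpgram_coarse": dpgram_summary(config.dpgram_f2_coarse_hz),
        "dpgram_fine": dpgram_summary(config.dpgram_f2_fine_hz),
    }


# ---------------------------------------------------------------------------
# Full run + report
# ---------------------------------------------------------------------------

def run(config: RunConfig, out_dir=None) -> dict:
    """Run both stages and assemble (optionally write) the report."""
    acoustics = run_acoustics(config)
    tables = acoustics.pop("_tables")
    physiology = run_physiology(config)
    report = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "acoustics": acoustics,
        "physiology": physiology,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        for name, table in tables.items():
            table.to_csv(out / f"{name}_syllables.csv", index=False)
    report["_tables"] = tables
    return report
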