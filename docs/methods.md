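# Methods

This note documents the models, parameters and numerical choices behind
`vocalrough`, the assumptions of its synthetic-data generators, and the
limits of what passing tests demonstrate about real recordings.

## The scientific question and the pipeline

Bat distress syllables often carry sinusoidal amplitude modulation (AM)
near 1.7 kHz. The pipeline quantifies that structure in three stages:
acoustic (does a syllable carry fast AM, and how does it differ spectrally
from syllables that do not?), stimulus construction (can the AM be removed
from a natural syllable without altering the rest of its design?), and
physiological (does the AM, and nothing else, drive heart-rate
acceleration and a frequency-following response in listeners?). Because no
recordings ship with the package, every stage is validated as a
parameter-recovery problem on synthetic inputs whose ground truth the
generator reports.

## Synthetic vocalizations

A syllable is a harmonic stack (default 3 harmonics, amplitudes 1/k) whose
fundamental follows one of three trajectories: a linear downward sweep
(`FM`, default 28 → 18 kHz), a quasi-constant-frequency plateau over the
first 40% of the duration followed by the sweep (`qCF-FM`), or a
sinusoidal trajectory around the band midpoint (`SFM`, 500 Hz rate, 5 kHz
depth). The modulator is `(1 + d·sin(2πft + φ)) / (1 + d)` — normalized so
the peak amplitude is depth-invariant, keeping level comparisons about
modulation rather than gain — with linear 0.3 ms edge ramps. Harmonic and
modulator phases are drawn from the seeded generator; everything is
bit-reproducible under a fixed seed.

Stimulus sequences repeat one syllable in 11 bouts of 6 with 14 ms
within-bout and 80 ms between-bout **silent gaps** (offset-to-onset): an
80 ms onset-to-onset inter-bout interval could not contain a six-syllable
bout, so the printed intervals are read as silences; an onset-to-onset
mode is available via `SequenceLayout.gap_mode`. Each copy is edge-faded
over 0.2 ms. A 5 ms syllable therefore renders to exactly
11·(6·5 + 5·14) + 10·80 = 1900 ms.

Corpora draw per-sequence syllable counts log-normally (median 60,
σ = 0.3 — the scale of natural distress sequences, without claiming their
distribution), label syllables fast-AM with the configured probability
(0.477 for distress-like, 0.063 for social-like corpora), and give fast
syllables AM rates ~N(1750, 200) Hz clipped to 1.2–2.4 kHz at depths
0.7–1.0. Slow syllables are either unmodulated or carry a sub-400 Hz
wobble at depth ≤ 0.5, so the slow class is not merely "silent envelopes".
A `position_bias` parameter weights fast-AM placement by
exp(−bias · normalized position), planting the left-skew that the position
analysis is meant to detect.

**What the generator does not emulate:** nonlinear phonation (subharmonics,
deterministic chaos), pulsatile (non-sinusoidal) modulators, recording
noise floors, reverberation, or sonar clicks. Consequences are flagged
below where they matter.

## Segmentation

A syllable is a maximal region where the detection envelope is at least
4.1% of digital full scale, with sub-threshold runs shorter than 1 ms
bridged and regions shorter than 0.5 ms dropped (an automatic stand-in for
the manual revision used on real data; configurable). The threshold is
referenced to full scale, not the per-file maximum, because the printed
4.1% is tied to a fixed recording chain. The detection envelope is a
**running maximum** of |x| over 0.1 ms: a moving average of the rectified
carrier would read ≈ 0.64× the true amplitude and silently shift the
effective threshold. Bouts group segments whose offset-to-onset gap is at
most 30 ms (the bout criterion is conventional; configurable).

## Acoustic features

**Envelope.** Magnitude of the analytic signal, low-passed below 5 kHz
(zero-phase 4th-order Butterworth) and resampled to a 0.1 ms grid. This
implements "envelope at 0.1 ms resolution" without reference to any
recorder-specific extraction; planted depths of 0.9 are recovered within
1%.

**TMS.** The mean-subtracted envelope is zero-padded to 1 s (fixing a 1 Hz
modulation grid across syllable durations), magnitude-squared FFT'd, kept
over 0–4 kHz, and normalized to unit total power. The BMF is the argmax
within the 1.15–2.45 kHz FOI band; the FOI area is the trapezoidal area of
normalized power over that band. Recovery of planted rates is within
~10 Hz (window smearing of a few-ms envelope shifts the argmax by a few
hertz; "within one grid step" of the 1 Hz padded grid is not attainable
and the 10 Hz feature grid is the meaningful resolution).

**Normalized vs absolute FOI power.** Because the TMS is normalized to
unit total fluctuation power, a *share* of power in the FOI band is only
meaningful when the envelope has substantial non-AM structure. Our
synthetic syllables have nearly flat coarse envelopes, so even a perfectly
unmodulated syllable shows an FOI share of ≈ 0.33 (its residual
fluctuation spectrum — ramp transients — is uniform, and the FOI spans
about a third of the 0–4 kHz grid). Demodulation quality is therefore
asserted on **absolute FOI envelope-modulation power** (mean square of the
FOI-bandpassed, mean-normalized envelope), which is gain-invariant and
drops by ≥ 98% after demodulation, rather than on the share, which cannot
drop below the flat-envelope floor.

**200 Hz spectra, HND.** The magnitude FFT is linearly interpolated onto a
200 Hz grid, peak-normalized; the HND is the maximum absolute difference
between the normalized spectrum and its 5-point moving average (shrinking
windows at the edges), making it dimensionless and gain-invariant. An
isolated unit line on empty background gives HND = 1 − 1/5 = 0.8; a flat
spectrum gives 0. Spectral area is reported in kHz of equivalent
full-power bandwidth. Band SPLs use a single-pass 3rd-order Butterworth
bandpass (the printed order, not zero-phase) referenced to a 94 dB SPL
calibrator through the full-scale calibration constant.

**Spectral autocorrelogram and MIPD.** The normalized spectrum is
autocorrelated **without mean subtraction** (scaled to 1 at lag 0), kept
to ±10 kHz, and local maxima are detected at prominence 0.025; the lag-0
global maximum counts as a peak, and the MIPD is the median of successive
inter-peak distances, undefined with no prominent off-zero maximum. Two
properties motivated this exact construction: on white-noise spectra the
un-subtracted positive baseline suppresses spurious prominent maxima
(≈ 8% of draws yield a defined MIPD, matching the expectation that the
procedure fails on noisy spectra), and a purely sinusoidal modulator
produces only first-order sidebands, i.e. exactly one off-zero peak —
counting lag 0 makes the 1.6 kHz spacing measurable in that case. Mean
subtraction plus a two-off-zero-peak requirement would make both
behaviors unattainable simultaneously.

**Sweep-rate regime.** For a linear FM sweep, the magnitude spectrum
follows the envelope imaged through the sweep (stationary phase), so its
comb spacing is `sweep_rate / am_rate` — about 1.0 kHz for the default
28 → 18 kHz / 6 ms syllable — *not* the AM rate. Spectral sidebands at the
AM rate dominate only when the carrier line width (sweep extent plus
1/duration) stays below the AM rate. The spectral-regularity analyses
therefore use a shallow-sweep syllable (28 → 27.5 kHz over 6 ms,
`shallow_fm_syllable_spec`), the regime in which spectral and temporal
regularity measure the same quantity — which is also the empirical regime
of the calls whose combs mirror their BMF. This is a genuine physical
limitation of MIPD on steep sweeps, not an implementation artifact.

## MPS analysis and demodulation

The STFT uses window 64, FFT 64, hop 1, periodic Hann, with the sound
centered in a 0.5 s zero buffer; at 192 kHz this gives 3 kHz bin spacing
and a temporal-modulation axis to ±96 kHz at ~2 Hz resolution — a geometry
chosen so that kHz-scale periodicity appears on the temporal-modulation
axis rather than folding into spectral modulations. The MPS is
log(|FFT2(log|STFT|)|²), with the log floored at 10⁻¹² of the maximum
magnitude; spectral modulations are expressed in cycles/kHz (linear
frequency axis). WOLA inversion at hop 1 is an exact identity
(round-trip error < 10⁻¹⁵ relative; unfiltered MPS resynthesis error
< 10⁻²⁰ %).

**Demodulation** nullifies the complex 2D-FFT coefficients for |temporal
modulation| ∈ 1–4 kHz across all spectral modulations. Two numerical
safeguards make this robust on deep-AM synthetics:

1. **Gate detrending.** The zero-padded buffer gives the log-magnitude a
   ~27-unit cliff at the syllable boundaries. Nullifying the cliff's
   in-band spectral content produces Gibbs ringing that the exponential
   amplifies into dominant edge artifacts (13–15% synthesis error, and
   residual FOI power re-created by harmonics of the ringing). A running
   median along the frame axis (window ≈ 1.2 periods of the lowest band
   frequency) tracks the gate but not the in-band modulation ripple; it is
   removed before and restored after the band nullification, so the filter
   acts on modulation content only.
2. **Magnitude-consistent phase refinement.** With hop 1 the STFT is
   64-fold redundant, and a single WOLA pass over inconsistent
   magnitude/phase pairs re-imposes part of the original envelope.
   Resynthesis therefore starts from the original phases and alternates
   WOLA synthesis with STFT re-analysis (8 projections), followed by
   quasi-Newton (L-BFGS, ≤ 60 iterations) descent on the
   magnitude-mismatch energy. All steps are deterministic.

The synthesis error is Σ(|S_desired| − |S_observed|)² / Σ|S_desired|²,
with the desired magnitudes those implied by the filtered log-STFT and the
observed ones from the STFT of the resynthesized sound. On the three
20 ms stimulus designs (AM 1.7 kHz, depth 0.9) the errors are FM 1.2%,
qCF-FM 1.2%, SFM 1.9% — all within the 2% gate that admits a sound as a
demodulated stimulus. Depth-0.9 AM is a hard case for log-domain
filtering: log(1 + 0.9 sin) has strong harmonics above 4 kHz that no
in-band filter can remove, which is why the refinement is needed at all;
natural sounds with shallower effective modulation are easier.

Demodulation preserves the spectro-temporal design: the monotone FM and
qCF-FM ridges correlate with their originals at r ≈ 0.995. The SFM
variant's 500 Hz frequency oscillation generates bin-crossing harmonics
that partly overlap the nullified band, so its trajectory is necessarily
smoothed (r ≈ 0.8–0.93); its dominant trajectory periodicity remains the
planted 500 Hz, which is the preservation property asserted for it.

Group contrasts between MPS maps use cell-wise Cliff's delta with
|d| > 0.474 marked as large (the threshold of the conventional binning;
a figure caption variant prints 0.478).

## Classification and position analysis

Feature vectors sample the TMS onto a fixed 0–4 kHz, 10 Hz grid
(401 points) and are scaled to unit L2 norm: level-invariant, and bounding
all pairwise squared distances by 2 so the RBF kernel at the default unit
kernel scale (box constraint 1, no standardization) remains informative —
with unit-*total-power* features the pairwise distances are ~10⁻², the
kernel matrix degenerates toward a constant, and cross-validation error
rises to ~6%. Training sets are 50 + 50 synthetic exemplars; fast-AM
training rates span 1.2–2.4 kHz (as hand-picked exemplars with pronounced
FOI periodicity would) except where a narrower band is explicitly under
test. Cross-validation is stratified, seeded, 10-fold. On well-separated
sets the CV error is ≤ 2%; corpus label recovery is ≥ 98% with the planted
fast-AM fraction recovered within ±0.02.

Normalized position of syllable i of N is (i−1)/(N−1) (N = 1 → 0.5; the
alternative i/N is available). The expected distribution pools fast-AM
positions over 100 within-sequence label permutations (label counts
preserved exactly, asserted at run time); observed vs expected is compared
by two-sample Kolmogorov-Smirnov, and per-sequence fast-AM proportions in
the first vs second half by Wilcoxon signed-rank. Under the null the KS
rejection rate at α = 0.05 calibrates to 0.05 ± 0.05.

## Physiology

**ECG.** Trials realize an instantaneous rate r(t) = baseline +
gain·g(t − onset), g a causal rise/decay kernel (0.5 s rise, 2 s decay
defaults); the k-th beat occurs when ∫r/60 crosses k, and each beat is
stamped with a biphasic, dominant-negative QRS template. The default
baseline is 480 beats/min, far below the 960 beats/min artifact bound.
Detection smooths |x| over 10 ms (one QRS width) and thresholds at the
envelope median plus k_sd = 2 envelope SDs — the spread is dominated by
the QRS bumps themselves, which places the threshold between the noise
floor's excursions and the beats; events refine to the raw-signal
extremum (recovery exact within ±1 ms at amplitude SNR 10).
Instantaneous HR is 60/interval at the later beat, linearly interpolated
to a 0.5 s grid over −5…+10 s. A trial is invalid if any interval drops
below 60/960 s ≈ 62 ms (instantaneous rate above 960 beats/min, the
movement-artifact signature; planted artifact bursts are spike triplets at
30 ms spacing and are rejected without loss of clean trials). The response
area integrates the baseline-subtracted curve over the first 10 s
(raw-area mode available); condition summaries average valid trials per
animal, z-score across condition means within animal for display, and
compare conditions by paired signed-rank across animals.

**iEEG.** Background is 1/f Gaussian noise; syllable windows add an evoked
damped transient plus a stimulus-locked sinusoid at the stimulus AM rate
(phase tied to global time). Spectrograms are DPSS multitaper (5 tapers,
NW = 3) over 50 ms windows at 5 ms steps — ~120 Hz bandwidth, resolving
the 1.6–2 kHz FFR band — baseline-corrected by subtracting the
per-frequency mean over the ≥ 1.5 s silent pre-stimulus span. FFR band
power is the mean corrected power in 1.6–2 kHz over the stimulus extent;
with the default planted gains it exceeds the control in every animal of
the synthetic cohort. Evoked averages take the 20 ms post-onset window
across syllables and trials; residuals shrink as 1/√N.

**DPOAE.** Ear-canal epochs contain the two primaries (f2/f1 = 1.25,
phase-locked across epochs) plus a cubic distortion product at 2f1 − f2
planted only when f2 ≥ 5 kHz — emulating a cochlea whose nonlinear
amplification fails below 5 kHz — and independent white noise per epoch.
Analysis averages epochs coherently, then reads amplitudes off a
Hann-windowed, 8× zero-padded spectrum (window sidelobes confine the
primaries' leakage; padding interpolates the main lobe so off-grid tone
amplitudes are read within ~0.1 dB — planted levels recover within
0.1 dB). The noise floor is the mean linear amplitude of 20 points (10 per
side) taken 40–100 Hz from the DP frequency: outside the windowed main
lobe but within a 100 Hz span. At the native 23.4 Hz resolution of an
8192-point epoch, 20 points cannot fit inside ±100 Hz, so the rule is
applied on the padded grid. Detection requires the DP to clear the floor
by 6 dB (configurable); DPgrams assemble results over coarse (1–25 kHz,
1 kHz steps) and fine (1–3.2 kHz, 0.2 kHz steps) f2 grids, and detection
tracks the planted cochlear cutoff exactly.

## Statistics

Cliff's delta is computed from the Mann-Whitney U statistic
(d = 2U/(n·m) − 1, tie-aware, O(n log n)); a brute-force pairwise
enumeration is retained and the two agree exactly on all inputs with
n·m ≤ 2500 (property-tested). Magnitude bins: negligible ≤ 0.147 < small
≤ 0.33 < medium ≤ 0.474 < large, boundary values falling to the lower bin
(the printed inequalities are strict). Paired comparisons use Wilcoxon
signed-rank (exact for n ≤ 25 without zeros or ties, normal approximation
otherwise — the library's own switch), unpaired use Mann-Whitney; both are
two-sided, type-I calibrated at α = 0.05 ± 0.02 in simulation, and an
all-zero paired difference returns NaN rather than a fabricated p-value.

## Problem sizes and determinism

Default desk-scale sizes: corpora of 30 distress + 15 social sequences
(≈ 2700 syllables), 12 ECG animals × 10 trials × 6 conditions, 11 iEEG
animals, 100-epoch DPOAE averages; the test suite uses smaller cohorts of
the same structure. All stages, including demodulation refinement, are
deterministic under the master seed, and identical configuration plus seed
reproduces reports byte-for-byte.

## Known limitations

- Absolute corpus fractions (47.7% / 6.3%) are *planted*, then recovered;
  on real recordings they depend on hand-picked training exemplars and are
  not reproducible from this package alone.
- MIPD on steep FM sweeps measures envelope imaging, not AM sidebands
  (see above); on real calls the measure is meaningful only in the
  shallow-sweep/harmonic regime, which the fixtures make explicit.
- The TMS FOI *share* saturates on flat-envelope synthetics; absolute FOI
  modulation power is the discriminative quantity in that regime.
- The ECG detector assumes QRS-dominated envelope spread; on a
  beat-free noise trace its threshold sits near the noise ceiling and
  isolated noise maxima can register as events.
- The demodulation's phase-refinement stage optimizes reconstruction
  fidelity, not perceptual indistinguishability; no auditory model is
  involved anywhere.
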