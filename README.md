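# vocalrough

Analysis pipeline for **fast amplitude modulations ("roughness-like"
structure) in bat distress vocalizations**, exercised end to end on
synthetic data with planted ground truth.

Distress calls of the bat *Carollia perspicillata* are harmonically
structured downward-FM syllables, many of which carry sinusoidal amplitude
modulation near 1.7 kHz — an acoustic analogue of the 30–150 Hz
"roughness" of human screams, an order of magnitude faster. This package
implements, as a tested library:

- **Syllable segmentation** by full-scale-relative amplitude threshold
  (4.1%, 1 ms gap bridging) and bout grouping;
- **Acoustic features**: amplitude envelope (0.1 ms resolution), temporal
  modulation spectrum (TMS) with best modulation frequency (BMF) and
  1.15–2.45 kHz band ("frequencies of interest", FOI) area,
  200-Hz-resolution spectra with peak frequency, spectral area and
  harmonic-to-noise difference (HND), spectral autocorrelograms with
  median inter-peak distance (MIPD), and calibrated band SPLs;
- **Modulation power spectrum (MPS)** analysis and filtering: hop-1 STFT
  (window 64, FFT 64) of sounds centered in a 0.5 s buffer, 2D-FFT of the
  log spectrogram, nullification of the 1–4 kHz temporal-modulation band,
  and weighted-overlap-add (WOLA) resynthesis — producing *demodulated*
  stimuli whose spectro-temporal design is preserved while the fast
  periodicity is removed, with a quantified synthesis error;
- **Syllable classification** (fast-AM vs slow-AM) by an RBF-kernel SVM on
  normalized TMS vectors, without feature standardization, plus the
  sequence-position permutation analysis;
- **Physiological response quantification**: QRS detection and
  heart-rate response areas with the >960 beats/min movement-artifact
  trial gate, DPSS multitaper (5 tapers, NW = 3) spectrograms with
  silent-baseline correction and 1.6–2 kHz frequency-following-response
  (FFR) band power, per-syllable evoked averages, and distortion-product
  otoacoustic emission (DPOAE) amplitudes with noise floors and DPgrams;
- **Statistics**: Cliff's delta with the conventional magnitude bins and
  Wilcoxon signed-rank / Mann-Whitney rank-sum tests;
- A **synthetic-data module** that generates every input with
  machine-readable ground truth (planted AM rates and depths, corpus label
  fractions, beat times, FFR gains, DP levels), so every analysis stage is
  testable as a parameter-recovery problem.

## Worked example

```python
from vocalrough import (SyllableSpec, make_syllable, demodulate,
                        amplitude_envelope, temporal_modulation_spectrum)

# a 20 ms downward-FM syllable with 1.7 kHz AM at depth 0.9
wave, truth = make_syllable(
    SyllableSpec(duration_s=0.020, am_rate_hz=1700, am_depth=0.9,
                 rate_hz=192000), seed=1)

tms = temporal_modulation_spectrum(amplitude_envelope(wave))
print(f"BMF = {tms.bmf_hz:.0f} Hz, FOI area = {tms.foi_area:.3f}")

demod, report = demodulate(wave)
tms2 = temporal_modulation_spectrum(amplitude_envelope(demod))
print(f"synthesis error = {report.synthesis_error_pct:.2f}%")
print(f"demodulated FOI area = {tms2.foi_area:.3f}")
```

prints

```
BMF = 1701 Hz, FOI area = 0.985
synthesis error = 1.18%
demodulated FOI area = 0.412
```

The TMS argmax recovers the planted 1.7 kHz modulation; demodulation
removes the modulation-band power (the residual normalized FOI share
reflects broadband edge transients — in absolute envelope-modulation power
the reduction exceeds 99%, see `docs/methods.md`) with a synthesis error
well below the 2% stimulus gate.

The full synthetic study — corpora, classification, position analysis,
ECG/iEEG cohorts, DPgrams — runs via

```bash
vocalrough run --seed 1 --out results/
```

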