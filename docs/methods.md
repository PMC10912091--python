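# Methods

## Overview

`adspect` implements an EEG analysis pipeline for multi-class classification of
the Alzheimer's disease spectrum — subjective cognitive decline (SCD),
non-amnestic and amnestic mild cognitive impairment (naMCI, aMCI), and AD —
from resting-state and auditory memory-encoding recordings. Because clinical
EEG of this kind is not freely redistributable, the package is driven by a
synthetic cohort generator that reproduces the statistical structure the
analysis assumes; every downstream stage is exercised and tested against that
generator.

The chain is:

1. **Cohort**: 58 subjects (20 SCD / 10 naMCI / 18 aMCI / 10 AD), each with a
   3-min eyes-open resting recording and three encoding sessions of nine
   2.5-s stimulus-locked trials (−500…2000 ms), 512 Hz, 36 electrodes in
   seven scalp regions (FM, LT, RT, CM, LP, RP, PM).
2. **Preprocessing**: common average reference; baseline correction over
   [−500, 0) ms for stimulus-locked trials; for rest, the centered 2-min
   segment cut into non-overlapping 2-s pseudo-trials. Zero-phase Butterworth
   band-pass (2–100 Hz, order 4) and IIR notch (60 Hz, Q = 30) filters exist
   for the real-data ingest path (EDF/BDF via mne, polyphase-resampled to
   512 Hz); synthetic data are generated band-limited at the target rate and
   skip them.
3. **Time–frequency decomposition**: complex Morlet wavelets, 42 center
   frequencies log-spaced over 2–60 Hz, cycle counts log-spaced 3 → 10.
   Three activities: *total* (trial-averaged single-trial power), *evoked*
   (power of the trial-average waveform, i.e. the phase-locked part), and
   *induced* (ERP subtracted from each trial before single-trial power).
4. **Features**: per activity, absolute power (AP, µV²) as the mean TF power
   in each of six bands (δ 2–4, θ 4–7, α 7–12, β₁ 12–19, β₂ 19–30, γ 30–40 Hz)
   × 400-ms windows, relative power (RP, %) as each band's share of the
   six-band sum, region averaging over the seven regions, and
   consecutive-window difference epochs. Encoding uses 6 base windows
   (−400–0 … 1600–2000 ms) + 5 differences = 11 epochs; rest has no
   pre-stimulus window: 5 + 4 = 9. Totals: 7·3·2·6·11 = 2772 features per
   encoding session, 7·3·2·6·9 = 2268 for rest.
5. **Selection**: per-feature one-way fixed-effects ANOVA over the four
   groups, keep p < 0.05 (no multiple-testing correction, by design); then a
   ridge regression (λ = 1) of one-hot group indicators on the standardized
   selected features, with the mean absolute coefficient across classes used
   as a multiplicative feature weight.
6. **Classification**: leave-one-subject-out (LOSO) cross-validation of nine
   classical models (2SVM, 3SVM, cKNN, EuKNN, partEns, narNN, wideNN,
   doubleNN, LDA); confusion matrix, per-class sensitivity / specificity /
   precision / F1 / one-vs-rest AUC, accuracy, macro-F1, Cohen's kappa.

## Synthetic cohort model

Background activity is 1/f^α Gaussian noise (α = 1), synthesized in the
frequency domain independently per channel and subject, each channel rescaled
to a target RMS (default 12 µV). Group structure enters through *effects*:

* **Evoked** effects are Hanning-windowed sinusoids at the band's geometric
  center frequency, at fixed latency and identical phase across trials —
  textbook phase-locked components that survive trial averaging.
* **Induced** effects use the same envelope with a fresh uniform random phase
  per trial — non-phase-locked power that vanishes from the ERP but not from
  per-trial power. Resting recordings receive only induced-type effects,
  realized as continuous oscillations with a random per-subject phase (there
  is no event to lock to).

Each effect is added equally to the electrodes of one named region and scaled
by `amplitude × per_group_gain[group] × jitter`, where the jitter is a
log-normal per-subject, per-effect factor (σ = 0.15). The jitter makes groups
overlap like real clinical populations instead of being noise-limited point
classes; without it, LOSO accuracy saturates at 100 %.

The default effect set encodes the study premise that task-locked activity
separates the groups more strongly than resting activity:

| state    | kind    | band  | region | window (ms) | gains SCD/naMCI/aMCI/AD | amp (µV) |
|----------|---------|-------|--------|-------------|--------------------------|----------|
| encoding | evoked  | theta | FM     | 0–400       | 1.8 / 1.4 / 1.0 / 0.6    | 6        |
| encoding | induced | alpha | PM     | 400–1200    | 1.6 / 1.4 / 1.0 / 0.7    | 6        |
| encoding | induced | beta2 | RT     | 600–1400    | 1.0 / 1.7 / 1.3 / 0.8    | 5        |
| resting  | induced | alpha | PM     | —           | 1.3 / 1.15 / 1.0 / 0.85  | 4        |
| resting  | induced | theta | FM     | —           | 0.85 / 1.0 / 1.15 / 1.3  | 4        |

The encoding set mimics a graded decline of the frontal evoked theta response,
an amnestic drop of induced posterior alpha, and a "compensatory"
right-temporal beta2 increase in the MCI groups; the resting set is the
classic slowing signature (posterior alpha down, frontal theta up with
severity) with a deliberately smaller spread. Gains and amplitudes are free
parameters of the artifact — physiologically plausible values chosen once and
documented here, not estimates of any real dataset.

All randomness flows from one integer seed through `numpy.random.SeedSequence`
spawning: one child sequence per subject (in cohort order), and per subject
separate streams for the gain jitter, the resting recording, and each
session. Identical `(spec, seed)` reproduce bit-identical recordings.
`generate_null_cohort` forces every per-group gain to 1 while retaining
labels, yielding group-exchangeable data as a negative control.

**What the generator does not emulate**: volume conduction / realistic
forward models, spatial noise correlations, ocular and muscle artifacts
(hence no ICA stage), non-stationary background dynamics, and behavioral
variability. Passing tests therefore demonstrate the correctness and
calibration of the *analysis*, not expected performance on clinical
recordings.

## Numerical choices

* **Wavelets**: Gaussian envelope σ_t = n_cycles/(2πf), truncated at ±4σ_t,
  amplitude normalized (scale 2/Σenvelope) so a stationary sinusoid of
  amplitude A yields power A² at its center frequency — matching the
  "power = squared amplitude" convention of the AP features.
* **Convolution**: trials are reflection-padded by half the longest wavelet;
  one forward FFT is shared across frequencies. Because the pad equals the
  maximal kernel half-length, circular convolution at the padded length is
  *exact* for the retained samples, so no further zero-padding is used. For
  signals too short to host the full pad, the FFT length is extended to make
  the convolution linear. The pipeline fast path accumulates coefficients in
  single precision (relative error ~1e-6, ample for band-averaged power);
  the individual operators default to double precision.
* **Evoked/induced identity**: the wavelet transform is linear and the ERP
  is the mean of the same trials, so mean|W_t − W̄|² = mean|W_t|² − |W̄|²:
  ERP-subtraction induced power equals total − evoked exactly, and neither
  can go negative (Jensen). Both methods are implemented literally and tested
  to agree; `tf_all` computes all three activities from one convolution pass
  using the identity.
* **Interval conventions**: half-open [lo, hi) for epoch windows, time
  windows, and band membership, with the top band closed at 40 Hz; a 2.5-s
  trial at 512 Hz has exactly 1280 samples. The printed band edges overlap at
  the boundaries, so a convention had to be fixed; it is applied uniformly.
* **RP denominator**: the sum of the six defined bands (2–40 Hz), not the
  full 2–60 Hz bank — "share of total power" is read as the six-band budget.
* **RP before region averaging**: RP is computed per channel and then
  region-averaged (the mean of percentages), treating the ratio as a
  per-feature attribute; difference epochs are computed on region-level
  values.
* **Zero-variance features** get p = 1 and a flag; an all-zero six-band power
  cell raises a degenerate-input error rather than producing NaNs; an empty
  post-selection feature set is refused at transform time.
* **Ties**: p-value ranking is a stable sort (ties resolve to canonical key
  order); kNN vote ties resolve toward the class earliest in the clinical
  order SCD < naMCI < aMCI < AD because labels are encoded as integers along
  that order.

## Selection and evaluation design

The default experiment nests screening, standardization, and ridge weighting
inside every LOSO training fold, so the held-out subject never influences any
fitted statistic. A `paper` mode fits the selection once on the full cohort
before cross-validation — the global-selection variant often seen when a
selection step is described before cross-validation without explicit nesting
— and is provided for sensitivity comparisons only; its estimates are
optimistically biased.

The evaluation reports test-fold results only. Chance levels are quantified
as the 95 % binomial quantile of the majority-class rate (20/58 → an upper
bound of ≈ 44.8 % accuracy for any label-independent classifier). On null
cohorts only this upper bound is asserted, because LOSO on exchangeable data
is pessimistically biased (the held-out subject's class is underrepresented
in its training fold), which can push null accuracy *below* the two-sided
chance interval.

Model hyperparameters are common presets, stated rather than tuned: kNN
k = 10; SVM C = 1, inhomogeneous polynomial kernels of degree 2/3, pairwise-
coupled probabilities; random-subspace ensemble of 30 LDA learners on
half-dimensional subspaces (the implementation draws ⌊d/2⌋ features);
networks with hidden layers (10), (100), (10, 10), log-loss, at most 1000
iterations, fixed seed.

The feature-count sweep (`f1_vs_nfeatures`) ranks features by ANOVA p value
within each training fold and classifies with the k best, ridge-weighted;
with k equal to the full feature count it coincides with an all-pass screen.

## Problem sizes used in tests and the acceptance script

Repeated-seed experiments (type-I calibration over 20 null cohorts,
encoding-vs-resting medians over 10 seeds) run the full 58-subject cohort
composition at a reduced analysis scale — 128 Hz sampling and a 12-frequency
bank — which leaves every statistical property intact while keeping the
suite fast. The costliest models (the subspace ensemble and the two larger
networks) use 3-seed medians. One
full-scale run (512 Hz, 42 frequencies, all three encoding sessions plus
rest) validates the default configuration end to end; the acceptance script
repeats that full-scale run from scratch at the seed it is given.

## Known limitations

* Real-data accuracies cannot be reproduced: the synthetic gains are free
  parameters, and reported numbers characterize the synthetic conditions.
* The ingest path performs no artifact correction; recordings must be clean.
* Induced power via ERP subtraction equals total − evoked here by linearity;
  pipelines that normalize per trial before averaging would break that
  identity, and no such normalization is applied (AP/RP operate on raw
  power, no dB or %-change baseline).
* The generator's effects are coherent within a region and independent
  across effects; no cross-regional covariance structure is modeled.
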