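# Methods

This note records the scientific and numerical conventions behind
`nirsfatigue`: what is modelled, which choices were genuinely open and how
they were fixed, and what the synthetic experiments do and do not show.

## Optical model

Continuous-wave fNIRS measures the attenuation of red (660 nm) and
infrared (860 nm) light between an emitter and a detector. The modified
Beer–Lambert law (mBLL) linearises attenuation changes around a reference
state: the optical-density change `OD^λ = log10(I_b^λ / I_t^λ)` is a linear
combination of the oxy- and deoxy-haemoglobin concentration changes,
weighted by extinction coefficients and the optical path length. Inverting
the resulting 2×2 system per sample yields ΔHbO2 and ΔHb; ΔHbt is their
sum.

Conventions:

* **Decimal logarithm.** The optical-density convention of the mBLL
  literature. The base only rescales all concentrations by a common
  factor (ln 10), which cancels in classification, but it must be pinned
  for numerical values to be comparable.
* **DPF = 1.** The differential path-length factor is unknown for this
  probe and identical at both measurement states, so it is factored out;
  concentrations carry units mM/DPF.
* **Extinction coefficients** (mM⁻¹ cm⁻¹): ε_Hb = 3.4408 / 0.7977 and
  ε_HbO2 = 0.3346 / 1.2071 at 660 / 860 nm (Matcher et al. compilation);
  emitter–detector distance 2 cm. All overridable via `OpticalConstants`.
* **Reference intensity I_b.** The mBLL needs a reference state. Default:
  per channel and wavelength, the mean intensity over the first 10 s of the
  pre-task baseline (`ReferenceIntervalPolicy(mode="first_k_seconds",
  k_s=10)`); the whole pre-baseline mean is available as an alternative. A
  fixed early reference keeps the two labelled baselines on the same scale.
  Samples where `I_t > I_b` are legitimate (negative OD) and are not
  clipped.
* The forward model `I_t = I_b · 10^(−OD)` is the exact algebraic inverse;
  the round-trip identity (error < 1e-10) is enforced by tests and is what
  makes the synthetic generator's ground truth meaningful.

## Preprocessing

* **Filter.** Second-order Butterworth band-pass, 0.01–1 Hz, designed in
  second-order sections and applied forward–backward (`sosfiltfilt`), i.e.
  zero phase with a squared magnitude response. A Butterworth design is
  inherently IIR; zero-phase application avoids group-delay distortion of
  the short windows that are featurised next. The band keeps the slow
  haemodynamic content and vasomotor waves while rejecting drift (< 0.01 Hz)
  and cardiac pulsation (≳ 1 Hz).
* **Windowing.** Windows are 10 s, non-overlapping, anchored at the start
  of each baseline period. A trailing partial window is dropped, and then
  the last complete window of every baseline is also discarded as a guard
  against task contamination, so a period of duration `T` yields
  `floor(T/10) − 1` windows. Exact 120-s baselines therefore give 11
  windows each, 22 per subject, balanced across classes. Task samples
  never enter any window.
* Periods are half-open `[start_s, end_s)` in seconds from recording
  start; sample indices are obtained by rounding `t × rate`.

## Features

Each of the six per-window series (2 channels × ΔHbO2/ΔHb/ΔHbt) is reduced
to 26 descriptors, giving the 156-column matrix. The feature list is fixed;
the discretisation choices that the names alone do not determine are:

* **Spectrum**: magnitude of the real FFT of the raw 1000-sample window
  (no detrending, no taper); 0.1 Hz resolution.
* **Fundamental frequency**: first local maximum above DC exceeding 20 %
  of the largest non-DC magnitude (`prominence_fraction`), else 0.
* **Maximum / median frequency**: smallest frequency at which cumulative
  power reaches 95 % / 50 %. **Power bandwidth**: span between the 2.5 %
  and 97.5 % cumulative-power points (the central 95 % of power).
* **Spectral distance**: sum of the cumulative magnitude spectrum minus
  its least-squares line over bin index.
* **Entropy** (temporal): Shannon entropy in bits of a 10-bin equal-width
  histogram over the window's range; 0 for constant windows. **Spectral
  entropy**: entropy in bits of the DC-excluded normalised power spectrum.
* **Kurtosis/skewness**: population (biased) moment estimators; kurtosis
  is Fisher excess. Constant windows return 0 for both.
* **Zero crossings**: strict sign changes between consecutive samples of
  the series as given (the filtered series are near zero-mean, so no mean
  centering is applied).
* **Polarity** (max/min): returns 0 with a warning when the minimum is
  exactly 0, to keep the matrix finite.
* **Variation features**: means of the ten 1-s blocks are differenced;
  maximum variation is the largest, minimum variation the smallest of
  those nine consecutive differences. (The two published descriptions of
  these features differ only in alignment wording; both reduce to the same
  difference sequence.)
* **Slope of linear regression** is against time in seconds (mM/DPF per
  second); the naive slope is last minus first sample.

## Classification

One model per subject ("user-tuned"): cognitive responses are individual
enough that pooling subjects is explicitly out of scope.

* **Forest**: 10 trees, bootstrap, Gini criterion, √p candidate features
  per node, `min_samples_split = 2` (trees grown to purity), majority
  vote; the positive-class score of a window is the fraction of trees
  voting *fatigue*. The forest is implemented as a compact numba-compiled
  engine (`nirsfatigue._forest`): the selection procedure below refits a
  forest after every single-feature elimination inside every internal
  fold — roughly 9,000 fits per subject on ~20-sample training sets — so
  per-fit overhead dominates runtime, and the compiled engine keeps a full
  subject evaluation near one second. Its statistical equivalence to a
  conventional implementation of the same ensemble is asserted in the test
  suite. Pinned tie-breaks: equal-gain splits go to the first candidate
  examined, tied leaves predict class 0, a tied 5/10 vote predicts class 0.
* **Feature selection**: recursive feature elimination with step 1 using
  the forest's impurity-based importances, run inside each outer fold on
  the training split only. Candidate feature counts are scored by internal
  stratified 5-fold accuracy; the best-scoring count wins, ties going to
  the smaller count, and a final elimination pass on the whole training
  split produces the selected set. The selected count varies from fold to
  fold. With only 10 trees the importance ranking is noisy — occasionally
  an informative feature receives zero importance in a refit and is
  dropped; this is inherent to the configured procedure (a conventional
  RFECV with the same forest behaves identically) and is why containment
  properties are tested as majorities over seeds.
* **Validation**: stratified 10-fold (shuffled, seeded); on 22 balanced
  windows this yields eight 2-window and two 3-window test sets. Fold
  predictions and scores are pooled before computing the confusion counts,
  accuracy, precision, recall and F1 (in percent, fatigue = positive) and
  AUC-ROC (rank-based on the pooled vote fractions, ties averaged).
  Degenerate denominators (e.g. no positive prediction in the pool) return
  0 with a warning instead of failing, since tiny folds make them
  reachable.
* **Aggregation**: across subjects, mean and *population* standard
  deviation (ddof = 0) per metric, plus the same statistics over the
  subset of subjects with accuracy strictly above 70 %.
* **Seeding**: one master seed per run; per-subject, per-fold and
  per-refit sub-seeds are drawn from a deterministic `SeedSequence`
  stream, making every report bit-reproducible.

## Synthetic generator

`SubjectSimSpec` emulates the acquisition protocol: 120-s pre-task
baseline, 600-s task block (generated but unlabelled, exercising period
slicing), 120-s post-task baseline, at 100 Hz. Each channel's ΔHbO2 is a
sum of a class-dependent sustained shift (−0.02 mM/DPF in the post
baseline; ΔHb +0.01), vasomotor (0.008 mM/DPF at 0.1 Hz), respiratory
(0.004 at 0.3 Hz) and cardiac (0.002 at 1.2 Hz) sinusoids with per-channel
random phases, optional linear drift, and white noise (sd 0.002 mM/DPF);
ΔHb carries half the oscillation amplitudes. Intensities follow by the
exact mBLL forward model from unit reference intensities.

Design points:

* **Observable fatigue signature.** The pipeline's own 0.01 Hz high-pass
  removes any constant offset between baselines 600 s apart, so a pure
  mean shift — however faithful to the raw physiology — is invisible to
  the classifier. The generator therefore also scales the vasomotor and
  respiratory amplitudes in the post baseline by `fatigue_osc_gain`
  (default 1.5), reflecting the altered low-frequency oscillatory power
  reported under sustained mental load. The effect-size knob scales the
  shifts and the gain excess together, so `effect = 0` is an exact null.
  The default amplitudes/noise were calibrated once so that the default
  effect is reliably recoverable (≥ 90 % pooled accuracy), then frozen.
* **Exact block means.** The default oscillator frequencies complete
  integer cycle counts over a 120-s baseline, so baseline block means
  equal shift + noise mean exactly; default drift is 0 (the knob exists)
  to keep that identity clean.
* **Cohorts** draw per-subject seeds from the base seed; the effect can be
  fixed for all subjects, listed per subject, or drawn uniformly from a
  range to emulate inter-subject variability.

What the generator does **not** emulate: motion artifacts, optode-coupling
changes, scattering/DPF variation, task-evoked responses, non-stationary
noise, or any validated magnitude of real fatigue-related haemoglobin
changes (the shifts are plausibility-driven simulation knobs). Passing the
recovery experiments therefore demonstrates that the pipeline is correct
and sensitive under its own assumptions — not that real recordings would
classify at these accuracies.

## Experiment sizes

The recovery experiments are sized to run comfortably on one CPU: the
strong-effect check uses one 10-subject cohort per run; the null control
averages 15–16 independent zero-effect subjects; the effect-size
monotonicity check uses 5 effect levels × 2 seeds. The chance band
[40 %, 60 %] for the null mean is the 3σ binomial envelope at these
replication counts.

## Known limitations

* The mBLL inversion assumes wavelength-independent path length and no
  scattering change; short-separation regression and motion correction are
  out of scope.
* The published per-subject accuracies on human data are not reproducible
  here — the study's recordings are not publicly deposited — so human-data
  claims are limited to the metric arithmetic that can be recomputed from
  the printed tables.
* With 22 windows per subject, all cross-validated estimates are coarse
  (1 window = 4.55 accuracy points); reported percentages should be read
  with that granularity in mind.
* Text-dialect files store one row per sample at 100 Hz and get large
  (~10 MB per 14-min subject); HDF5 is preferred for cohorts.
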