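# Methods

`spikeloc` tests whether a single neuron's spike train carries a decodable
signature of its anatomical location (brain region, structure within a
region, VISp-vs-secondary visual cortex, cortical layer), and packages the
complete analysis chain: featurization → split design → imbalance-corrected
classification → electrode-consensus smoothing → evaluation →
interpretation.  This note records the models, the defaults and why they
are what they are, and what the synthetic benchmark does and does not show.

## Data model

A *unit* is a well-isolated neuron with sorted spike timestamps (seconds),
anatomical labels, an integer electrode index giving its position along a
linear probe, and spike-sorting quality metrics.  All time intervals are
half-open `[start, stop)`; duplicate or unsorted spike timestamps are
rejected at load rather than repaired, because downstream interspike
intervals must be strictly positive and silent repair would mask upstream
sorting problems.

Inclusion filters follow standard extracellular quality practice: ISI
violations < 0.5, amplitude cutoff < 0.1, presence ratio > 0.9 (strict
inequality at the boundary), and firing rate ≥ 0.1 Hz.  Rate is computed
over the supplied analysis window — the package never sees more session
than it is given, so the window stands in for "the session".  Classes
(regions or structures) with fewer than 150 units are removed, which
guarantees roughly ≥ 30 test units per class under the 60/20/20 split.
Units with missing or ambiguous structure labels are excluded from
structure-level tasks but kept for region tasks.

## Representations

* **metrics14** — CV2, LV, LVR (refractoriness constant R = 5 ms), mean
  firing rate, SD/CV/min/median/max of the ISIs, and five periodogram
  band-power ratios (delta 0.1–4 Hz, theta 4–8, alpha 8–12, beta 12–40,
  gamma 40–100).  The PSD uses 1 ms count bins (1 kHz sampling), a plain
  one-sided boxcar periodogram with no detrending, computed directly from
  the FFT.  Each band feature is the *mean* periodogram value in the band
  normalized by the sum of the five band means, so the features sum to 1.
  The mean (rather than the integral) keeps a 4 Hz-wide oscillatory band
  comparable with the 60 Hz-wide gamma band: a periodic train peaks in the
  band holding its fundamental rather than in whichever band collects the
  most harmonics.  A flat (Poisson) spectrum consequently gives all bands
  ≈ 1/5.
* **isi_dist** — ISI histogram on [0, 3) s, default 300 bins of 10 ms,
  per-unit min-max normalization (a constant histogram maps to all-zeros).
  Both the bin count and the lower edge are configurable because published
  variants of this featurization differ (100 vs 300 bins, 0 vs 1 ms lower
  edge); the default is 300 bins from 0.
* **avg_psth** — counts in 100 uniform bins over the 3 s grating trial
  (1 s gray + 2 s stimulus), averaged over all 600 trials, min-max
  normalized.
* **cat_psth** — a 30-bin PSTH per grating condition, min-max normalized
  per condition *before* concatenation, ordered orientation-major ascending
  then temporal frequency ascending (the ordering is fixed and documented
  so trained models are portable): 8 × 5 × 30 = 1200 features.

Units with fewer than 3 spikes in the context window are dropped from
featurization with a logged reason.

## Split design

The 60/20/20 train/validation/test requirement with every unit tested
exactly once and validated exactly once is realized as a 5-group rotation:
units are dealt round-robin into five near-equal groups; fold *i* tests on
group *i* and validates on group *i+1 (mod 5)*.  Transductive plans deal
within each (animal, class) cell, continuing the deal across animals so
that classes stay stratified even when a cell has fewer than five units;
inductive plans deal whole animals (≥ 5 animals required), so a fold's
test animals never contribute training units.  Cross-dataset plans train
80/20 (stratified) on one dataset restricted to the class intersection and
test on all of the other.

## Classifiers

* Logistic regression: multinomial, L2 penalty, tolerance 1e-4.  Features
  are z-scored with training-set statistics (this changes coefficients,
  not accuracy, and makes the L2 penalty scale-free); constant features are
  dropped with a warning.
* MLP: one hidden ReLU layer trained with Adam.  The search grids per
  representation: hidden nodes 50–600 step 50 (30–300 for the average
  PSTH), learning rate decades 1e-7…1e-1 (1e-5…1e-1 for PSTHs), batch size
  25–475 step 50 (50–600 for PSTHs), L2 strength 1e-4…10 (…1 for PSTHs),
  Adam beta1 0.5–0.9 step 0.1.  Early stopping monitors validation
  *balanced* accuracy with patience 10 over at most 200 epochs (60 in the
  pipeline defaults), restoring best-epoch weights; the schedule is a
  bounded desk-scale default, not a tuned quantity.
* Class imbalance: the training set is resampled before fitting; the
  default is SMOTE — every minority class is upsampled to the majority
  count with samples `x + u·(x_nn − x)`, `u ~ U(0,1)`, between a minority
  point and one of its k = 5 Euclidean nearest minority neighbours.
  Undersampling, plain oversampling and no resampling are selectable and
  may be searched as a hyperparameter.  A singleton class falls back to
  duplication with a warning.
* Hyperparameter search: seeded random search over the grids, maximizing
  validation balanced accuracy; the strategy is pluggable and an
  exhaustive mode exists for small grids.  Every trial is logged and the
  returned point attains the logged maximum.

Predicted probabilities are emitted as a per-unit table with a fixed class
order; winner-take-all ties break deterministically to the lowest class
index.

## Electrode-consensus smoothing

Anatomy is contiguous along a probe, so isolated misclassifications can be
corrected by their neighbours.  Per probe: class probabilities are averaged
over the units of each occupied electrode; each occupied electrode's vector
is then replaced by the convex combination of occupied-electrode vectors
with Gaussian weights `pdf(e′; mean e, sd σ)`, renormalized over occupied
electrodes only (unoccupied electrodes take part in neither weighting nor
targets).  Probes are never smoothed into each other, distances are in
electrode-index units, and the probability simplex is preserved exactly.
σ is tuned on validation balanced accuracy over a log-spaced range
[0.5, 50] with budget 20.  The smoothing gain is a direct test of the
stochastic-error hypothesis: it helps exactly when errors are spatially
uncorrelated while anatomy is not, and a shuffled-anatomy control gains
nothing.

Hierarchical (region → structure) classification routes each unit by its
smoothed region winner to that region's structure model (midbrain is
terminal); on the canonical atlas this yields 19 labels (18 structures
plus midbrain).  Cross-regional errors are a structural consequence of
routing: a unit mis-routed to the wrong region necessarily receives one of
that region's structures.

## Interpretation

* Permutation importance (ISI bins or whole 30-bin condition blocks):
  baseline error is computed on the test units of one class; the feature
  (or block) is shuffled across *all* test units and the class-subset error
  recomputed; importance is the mean error increase over repetitions.
  Shuffling across all units is essential — a within-class shuffle
  preserves the class marginal and reports no importance even for a
  perfectly informative feature.  The error metric is 1 − class
  sensitivity (configurable to 1 − accuracy).  Sub-seeds per feature are
  derived from the master seed.
* Duration sensitivity: test spike trains truncated to `[t0, t0 + d)`
  (t0 = stimulus-block start by default), ISI features recomputed, per-class
  sensitivity reported per duration; over-long durations use all data and
  are flagged.
* ISI-window statistics: per unit, mean and variance of the *raw* ISIs in
  a window plus the OLS slope of the min-max-normalized histogram against
  bin centers there; class-vs-rest two-sample t-tests are
  Bonferroni-corrected across the three statistics and effect sizes are
  reported as |Cohen's d| with the pooled SD.

## Synthetic data generator

The generator emulates the features of multi-animal Neuropixels recordings
that the analysis relies on, without any biophysics:

* Spike trains are inhomogeneous gamma-renewal processes built by time
  rescaling: ISIs are gamma(κ, mean 1/κ) in rescaled time, mapped through
  the inverse integrated rate (piecewise linear for the piecewise-constant
  rate).  κ controls regularity (κ = 1 Poisson-like, CV = 1/√κ), which is
  the axis the CV2/LV/LVR statistics measure; renewal-by-rescaling was
  chosen over Poisson thinning precisely so that regularity is a
  controllable, structure-specific parameter.
* Each of the 12 default structures (4 regions) has its own base rate,
  κ, orientation preference and concentration, temporal-frequency
  preference and bandwidth, and modulation depth; tuning is von Mises in
  orientation × log-Gaussian in frequency, normalized to mean 1 over the
  40 conditions so the modulated rate stays positive for modulation depth
  ≤ 1.  Values are physiologically plausible (hippocampus slow/bursty,
  thalamus fast/regular, cortex orientation-tuned) but not fit to any
  recording.
* The stimulus protocol is the canonical session: a 30 min gratings block
  of 8 orientations × 5 frequencies × 15 three-second trials (1 s gray +
  2 s stimulus) in pseudo-random order, then 20 min of untuned movie
  epochs (rate × 1.15) and 20 min of spontaneous activity (rate × 0.85).
* Per-animal idiosyncrasy: log-normal factors (SD 0.2 in log space) on
  rate and κ shared by all of an animal's units, a per-animal rotation of
  orientation preferences (SD 20°), and a per-animal stimulus-response
  latency (50 ms baseline plus half-normal jitter with SD 80 ms, capped at
  500 ms) that delays the rate step at grating onset.  The rotation and
  latency matter: per-unit min-max normalization removes pure rate scaling
  from PSTH features, so without a shape- or timing-level animal signature
  inductive and transductive PSTH decoding would coincide and the
  generalization gap the split design probes would not exist in the
  benchmark.
* Structure parameters are calibrated so that between-region differences
  dominate within-region ones: regions differ roughly two-fold in rate and
  span bursty (κ ≈ 0.5) to clock-like (κ ≈ 3), while structures of one
  region share a timing phenotype and the secondary visual areas differ
  mostly in stimulus preference.  This is what makes the region task
  easier than the structure tasks and leaves the visuocortical structure
  task closest to chance — the difficulty ordering the benchmark is meant
  to reproduce.
* Geometry: 8 animals × 2 probes; each probe traverses its structures in
  contiguous spans of 20 electrodes, so anatomical labels are spatially
  contiguous and smoothing has structure to exploit.  An optional
  `label_noise_rate` flips that fraction of recorded labels to a random
  wrong structure (spike statistics keep their true parameters) for
  smoothing experiments.
* 150 units per structure by default, so the default class filter passes;
  quality metrics are drawn from comfortably passing ranges.  All
  randomness flows through one seeded generator; a fixed seed reproduces
  the dataset exactly.

What passing on this benchmark does *not* show: the generator has no
bursting dynamics, no movie-frame-locked modulation, no electrode drift,
no correlated noise between neighbouring units, and its class
separability is chosen rather than measured, so absolute accuracies on
synthetic data say nothing about absolute accuracies on recordings — only
the contracts, orderings and invariances carry over.

## Numerical choices and degenerate inputs

* Min-max of a constant vector is all-zeros.
* MCC with an undefined denominator (single observed or predicted class)
  is 0 with a warning.
* Balanced accuracy excludes classes with no true samples (warning when an
  explicit class order was given).
* Argmax ties break to the lowest class index everywhere.
* The master experiment seed fans out to per-stage sub-seeds via SHA-256
  of `(seed, stage, index)`, keeping stages independent and reproducible.
* Test problem sizes: the suite runs the full default generator (1800
  units, full gratings block) for the decoding checks and smaller
  configurations (36–60 units per structure, 2–5 grating repeats)
  elsewhere; these sizes are the package's own desk-scale choices.

## Known limitations

* Bayesian hyperparameter search is random search here; with a handful of
  grid dimensions and desk-scale budgets the difference is modest, and the
  strategy is pluggable.
* Probe geometry is strictly linear (integer electrode index); 2-D layouts
  and micrometer coordinates are out of scope.
* NWB ingestion is an adapter seam only: export the three interchange
  tables and call `load_dataset`.
* The mixed-effects significance machinery for comparing model variants
  across splits is deliberately not included; fold-level scores are
  reported as mean ± SEM.
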