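# Methods

## The estimand and the two protocols

Given a samples × features matrix `X` (n samples, d features, d ≫ n) with
binary labels, the quantity of interest is the cross-validated prediction
accuracy of a linear classifier restricted to a data-driven feature subset.
Two pipelines compute it:

* **outside-CV (leaky)**: per-feature z-scoring and the vote-threshold
  selector use all n samples; repeated stratified k-fold CV then estimates
  the accuracy of classifiers restricted to the resulting fixed subset.
  Every CV test sample has already influenced both the scaling and the
  subset, so the estimate is biased upward (selection bias / data leakage).
* **within-CV (nested)**: in each CV loop, z-score statistics are fitted on
  the training folds and applied to the test fold, the selector sees the
  training folds only, and the classifier is trained on the selected
  training features. The test fold never influences any fitted quantity;
  this is verified by a taint test (perturbing test-fold values leaves the
  loop's selected set and trained weights bit-identical).

The difference between the two estimates measures the inflation caused by
performing selection outside CV.

## Vote-threshold selection

Per repetition r = 1…R (default R = 100), draw ⌊f·n_c⌋ samples per class
(f = 0.8) without replacement and test every feature with an unpaired
two-sample t-test (Student pooled-variance by default; Welch optional). A
feature earns a vote when p < α (default 0.05). Selection keeps features
with ≥ T votes; ranking orders by votes (desc), then mean p-value across
repetitions (asc), then feature position — a total order that makes sweeps
deterministic. Degenerate zero-variance cells return (t = 0, p = 1) when the
group means agree and (±∞, 0) otherwise, so resampling never crashes on
constant features.

All R repetitions are computed in one pass: 0/1 subsample indicator matrices
give per-repetition group sums and sums of squares as two matrix products,
from which every (repetition, feature) t statistic follows vectorized.
Corrected sums of squares are clipped at zero to guard against catastrophic
cancellation; `scipy.stats.ttest_ind` is kept off this code path so the test
suite can use it as an independent oracle (agreement to ≥ 10 significant
digits).

**A structural property worth knowing:** because all repetitions subsample
the *same* data at f = 0.8, their p-values are strongly correlated; a
feature's vote count is close to a monotone function of its full-sample
p-value rather than a Binomial(R, power) draw. On pure-noise data ≈ 3% of
features therefore reach 50 votes and ≈ 0.4% reach 90 votes — a "null
floor" on the selected-set size that no generator setting can push below.
This floor is why the leaky protocol fixes hundreds (not dozens) of features
at lenient thresholds on the default simulation, and it correspondingly
enlarges the leaky inflation.

## Classifiers

* **SVM**: soft-margin linear SVM (hinge loss), cost C = 1 — features are
  z-scored and post-selection dimensionality is modest, so the default cost
  is left at the conventional value; configurable.
* **RLDA**: class means μ₀, μ₁; pooled within-class covariance S (divisor
  n − 2); shrinkage target (tr S / d)·I; S_γ = (1 − γ)S + γ·target;
  discriminant w = S_γ⁻¹(μ₁ − μ₀) with intercept −wᵀ(μ₀ + μ₁)/2 (equal
  priors — the designs here are balanced). γ = "auto" uses the Ledoit–Wolf
  analytic intensity estimated from the class-centered training residuals,
  keeping the rule well-posed when d approaches or exceeds n; fixed γ ∈
  [0, 1] is available, and γ = 0 on rank-deficient data is rejected with
  guidance rather than silently regularized.
* Ties on the decision boundary go to class 1, fixed by contract.

## Cross-validation plan

Stratified k-fold (default 10 folds, 10 repetitions), reshuffled
independently per repetition; per-fold class counts stay within one of
proportionality. Accuracies are aggregated as the simple mean over the 100
fold accuracies (folds are near-equal size under stratification). Within-CV
selected-set sizes are reported as min–max ranges over loops. An empty
selection in a loop falls back to the single top-voted feature (counted and
logged); an empty selection in the leaky protocol drops that threshold with
a warning.

Seeds are explicit and separate for data generation, subsampling and fold
assignment; all three derive from one master seed, and fixed seeds make
every run — including the end-to-end config-driven experiment — 
bit-reproducible.

## Synthetic data

**Gaussian grid simulator.** d = 6,424 features for 58 samples per class by
default (mirroring a 58 + 58 clinical cohort). Per feature, a (mean,
variance) pair is drawn uniformly from the grids {0, 0.1, 0.2, 0.3} ×
{0.1, 0.2, …, 2.3} and, by default, **shared by both classes**, so every
feature is null and any leaky-protocol gain over 50% is pure selection bias.
The wording such simulations are usually described with ("a pair of mean and
variance was selected to generate a feature vector") is ambiguous between
this shared draw and independent per-class draws; we examined both and kept
the shared draw as default because the per-class variant floods the problem
with ≈ 4,800 genuinely separated features — every protocol then saturates
near 100% and the design stops being a leakage demonstration. The per-class
mode (`per_class_draw=True`) is retained as a tested option for
strong-signal experiments, as is a continuous-uniform draw over the grid
ranges (`grid_mode="continuous"`).

**No-signal control.** `generate_null_features` is the explicit null
generator (one pair, both classes) used by the bias property tests.

**Connectivity generator.** Emulates phase-locking-value (PLV) tables:
features are all C(45,2) channel pairs × 6 bands (delta 1–4, theta 4–8,
alpha 8–12, low-beta 12–22, high-beta 22–30, gamma 30–55 Hz) = 5,940 edges
over a standard extended 10–20 45-channel montage (configurable labels).
Edge values are generated as logistic(N(μ, σ)) on the logit scale
(μ = −0.4, σ = 0.6 by default, giving PLVs centered near 0.4), which
guarantees the [0, 1] PLV range; planted group effects are logit-scale mean
shifts on chosen edges (default: three frontal theta/gamma edges, shift
1.5 ≈ a +0.3 PLV shift — "strong" on Cohen's d scale). What it does *not*
emulate: the spatial correlation structure of real scalp EEG (neighboring
edges sharing channels are correlated in vivo, independent here), volume
conduction, within-subject nonstationarity, or any signal-processing chain
from raw time series to PLV. Passing tests on this generator therefore
validate the pipeline's bookkeeping and bias mechanics, not claims about
real EEG effect topographies.

## Overlap analysis

Per CV loop ℓ of the nested protocol, the overlap ratio is
|outside ∩ withinℓ| / |withinℓ|, averaged over loops (a union-denominator
variant is available). Edge categorization against a selection-frequency
cutoff (default 50 of 100 loops): `shared` (in the fixed set and ever
selected), `within_only_high` (never in the fixed set, frequency ≥ cutoff),
`within_only_low` (never in the fixed set, frequency below cutoff);
frequency exactly at the cutoff counts as high. Categories partition the
union of ever-selected and fixed-set features.

## Problem sizes and statistical behavior of the estimates

The default experiment (6,424 features, 116 samples, five thresholds, both
classifiers, 10×10 CV) runs in under a minute per protocol on one CPU; the
test suite exercises full-size runs for the study-level checks and
scaled-down configurations (hundreds of features, tens of samples, 2–5
folds) everywhere else — chosen as the smallest sizes at which the effects
under test are comfortably larger than Monte-Carlo noise.

Two behaviors of the *nested* estimate deserve emphasis. First, conditional
on one dataset, its 100 fold accuracies are far from independent: every
sample is reused as a test point once per repetition, so the effective
sample size of the mean is ≈ n, not 100 × fold size. On null data the
nested mean therefore scatters around 50% with an SD of several percentage
points across dataset realizations; bands built from the naive binomial
standard error over 100 folds are anti-conservative by roughly a factor of
three. Second, on shared-draw (null) data any apparent structure the nested
sweep shows — dips below chance, slow drifts with k — is this same
dataset-level fluctuation, not signal.

## Known limitations

* The leaky protocol's inflation size depends on the null floor of the vote
  process (see above): at lenient thresholds it fixes ~150–200 noise
  features, pushing leaky accuracy into the 90s on null data. Configurations
  reported elsewhere with only a few dozen selected features at the same
  thresholds are not reachable by this vote process on i.i.d. Gaussian
  features.
* Equal class priors and balanced designs are assumed throughout; the RLDA
  intercept and the stratification logic would need adjustment for
  imbalanced cohorts.
* Only linear classifiers and a single selection family (subsample t-test
  votes) are implemented; wrapper selectors (e.g. recursive feature
  elimination) are out of scope.
* Sweep and protocol runtimes scale linearly in loops × thresholds (or k);
  the implementation is single-threaded numpy/BLAS.
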