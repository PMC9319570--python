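# Methods

This note documents the models, estimators and numerical choices behind
`harpipe`, the defaults that matter and why, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Problem setting

Input is tri-axial acceleration (units of g) sampled at 100 Hz per subject
and sensor location (left wrist, left hip, left ankle, right ankle), with a
per-sample activity label from {level walking, ascending stairs, descending
stairs, driving} plus transition/non-study markers. The task is group-level
(cross-subject) classification of the four activities under severe class
imbalance: driving dominates and the two stair classes are a few percent of
the corpus each.

## Epoching

Features are computed on 5-s windows (500 samples) slid with a 1-s hop, i.e.
4-s overlap, so a prediction is available every second. Windows are
sample-count based and closed on the left; no resampling is performed. A
window is kept only if **all** of its samples carry the same one of the four
activity labels — any transition, non-study or second-activity sample
excludes it (unanimity, not majority). Partial tail windows are dropped. The
hop is configurable; `hop_s = window_s` recovers non-overlapping 5-s
cadence.

## Feature set (25 per axis, 75 per epoch)

Per-axis column order: RMS, σ, skewness, kurtosis, zero crossings,
peak-to-peak, Hjorth mobility, Hjorth complexity, PP1–3, DF1–3, total
energy, spectral entropy, band PP/DF/TE/SpecEn, Hurst, AMI, FNN, Lyapunov,
SampEn; the x, y, z blocks are concatenated in that order.

### Temporal

All moments use population (1/n) normalization; kurtosis is non-excess
(Gaussian → 3). Hjorth mobility is sd(Δx)/sd(x), complexity is
mobility(Δx)/mobility(x). Zero crossings are counted as
½ Σ|sgn(xᵢ) − sgn(xᵢ₋₁)| with sgn(0) = 0, **on the mean-removed signal** by
default: the count serves as a fundamental-frequency proxy, and a constant
gravity offset (≈1 g on the vertical axis) would otherwise pin the raw
signal on one side of zero. `detrend=False` restores the literal raw-signal
count. Constant inputs return 0 for the shape and Hjorth features with a
logged note instead of raising.

### Spectral

Each epoch is a single analysis frame: mean-removed, Hamming-windowed,
Fourier-transformed; the squared magnitude gives the PSD with bin spacing
1/window_s = 0.2 Hz. The DC bin is excluded and bins up to 15 Hz kept — 75
bins at the defaults (15/0.2 = 75 only without DC). The 1-s epoch hop
realizes the sliding of a short-time Fourier transform, so no within-epoch
(Welch) averaging is applied.

Numerical choices, each where more than one reading was defensible:

* **Spectral entropy** uses the probability-normalized PSD,
  −Σ p_f log₂ p_f with p_f = P_f/ΣP_f, making it scale-invariant and
  interpretable as randomness of the spectrum (0 … log₂ 75 bits). The
  unnormalized −Σ P_f log₂ P_f form is available via
  `normalized_entropy=False`.
* **Peak powers** PP1 ≥ PP2 ≥ PP3 are the three largest *bin values* (not
  local maxima), ties broken toward lower frequency; their frequencies are
  reported re-sorted ascending as DF1 < DF2 < DF3. PPᵢ and DFᵢ are therefore
  deliberately decoupled. Note a consequence: for a pure bin-centered tone
  the Hamming main lobe occupies three adjacent bins, so the DF triple is
  (f−0.2, f, f+0.2).
* **Band features** use bins strictly below 2.5 Hz (0.2–2.4 Hz, 12 bins).

### Nonlinear

* **Embedding delay τ** — first local minimum of the auto mutual
  information curve, estimated from a 16×16 equal-width 2-D histogram over
  lags 0–100 samples (1 s). 16 bins is a standard bias/variance compromise
  at n = 500; the plug-in MI bias for independent data is ≈ bins²/(2n ln 2)
  ≈ 0.09 bits, which the independence tests account for. Monotone curves
  fall back to the argmin, flagged.
* **Embedding dimension d** — Kennel-style false nearest neighbors: each
  delay vector's nearest Euclidean neighbor is false when the coordinate
  gained at dimension d+1 moves the pair apart by more than R_tol = 15 times
  their d-dimensional distance. An absolute floor (10⁻⁸ × sd) keeps
  exactly-recurrent points of noise-free periodic signals (distances at
  rounding level) from being flagged. d is the smallest dimension whose
  false fraction is ≤ 1% ("dropped to zero") and does not drop further by
  more than 1% at d+1; fallback is max_dim = 10, flagged.
* **Largest Lyapunov exponent λ** — nearest-neighbor divergence tracking:
  embed with (τ, d), pair each point with its nearest neighbor at least one
  mean period away in time (mean period from the dominant frequency), track
  the mean log separation over a horizon of min(mean period, 30) samples
  (at least 5), and take the least-squares slope. Reported per sample;
  multiply by the sample rate for s⁻¹. Validated against ln 2 ≈ 0.693 per
  step for the fully chaotic logistic map (r = 4) and against ≈0 for a pure
  sine; a literal loop-based divergence tracker in the test suite confirms
  the vectorized estimator to 10⁻⁹ on toys.
* **Sample entropy** — −log(A/B) with B the number of template pairs
  (i < j, self-matches excluded) within Chebyshev distance R at length m and
  A the same at m+1. Defaults wired in the pipeline: template delay = τ,
  m = min(d, 3), R = 0.2 × epoch sd (making the feature affine-invariant).
  Zero match counts return NaN, flagged.
* **Hurst exponent** — rescaled range: for window sizes on a dyadic grid
  (16, 32, …, n/2), each non-overlapping segment contributes
  R/S = ptp(cumsum(x − mean))/sd; H is the slope of log mean(R/S) against
  log window size. At n = 500 the estimator carries the well-known
  small-sample positive bias (mean ≈ 0.56 for iid noise rather than 0.50);
  no Anis–Lloyd correction is applied, and the iid-noise oracle tolerance
  (±0.1) covers the bias.

The exported AMI feature is the AMI value at τ and the exported FNN feature
is d itself; τ and d additionally parameterize λ and SampEn. Flagged (NaN)
nonlinear values are imputed with the training-fold feature median inside
the model scaler, logged.

## Class balancing

Applied to training folds only, strictly after the subject split.

* **Random undersampling** deletes uniformly chosen rows from every larger
  class until all classes match the minimum count; minority rows are never
  touched. Because the deletion is random, it is repeated 10 times with
  derived seeds and downstream metrics are averaged at the metric level (not
  pooled predictions).
* **SMOTE** raises every non-majority class to the majority count. Each
  synthetic row is x + u·(x_nn − x) with u ~ U(0, 1) and x_nn one of the
  k = 5 nearest same-class neighbors; the neighbor search runs in z-scored
  feature space (using the training-fold scaler) because Euclidean distance
  across raw feature scales is meaningless. k is clipped to class size − 1
  for tiny classes; singleton classes are an error.

## Classifiers

All models see median-imputed, z-scored features (scaler fit on the training
rows only; the test for scaler leakage asserts the stored means equal the
training means exactly). Defaults: random forest = 100 trees grown to
purity, ⌈√75⌉ = 9 features per split, majority vote with ties to the lowest
class index; AdaBoost = 100 sequentially reweighted depth-3 trees with
SAMME-style multiclass updates; decision tree (unpruned), 3-NN, LDA, QDA,
linear-kernel SVM (C = 1, one-vs-one), MLP with one 64-unit hidden layer and
early stopping. The ensemble fits are delegated to scikit-learn; prediction
and importance are verified against brute-force tallies over the exported
tree structures.

## Gini feature importance

For every split node N_k with children N_kl, N_kr and reach probabilities
p (weighted fraction of training samples reaching the node):

  contribution(N_k) = p_k·Gini(N_k) − p_kl·Gini(N_kl) − p_kr·Gini(N_kr)

attributed to the split feature, where Gini(N) = 1 − Σᵢ pᵢ². Per-tree
feature totals are divided by **that tree's node count** and averaged over
trees; the alternative reading (divide by the total node count across the
forest) is available via `denominator="forest"`. This normalization differs
from scikit-learn's `feature_importances_` (per-tree sums normalized to
1), so the scores are computed directly from the fitted tree structures;
the rankings correlate strongly (Spearman ρ > 0.9 in tests). Contributions
are non-negative for impurity-greedy splits, which the tests assert on
fitted forests. Fitted ensembles serialize to a JSON structure (spec +
scaler + tree node arrays) from which both importance and majority-vote
prediction are recomputable without scikit-learn objects.

## Evaluation

Subjects are randomly partitioned into 8 folds (28 train / 4 test at the
reference 32-subject size; remainders are spread one per fold). Metrics
follow the one-vs-rest definitions; balanced accuracy is the arithmetic mean
of per-class recalls (asserted to 10⁻¹² against hand-built confusion
matrices), and `minority_avg_recall` averages the two stair-class recalls.
Classes absent from a fold's truth get NaN recall and are excluded from the
mean, logged. Cell failures in the experiment grid are isolated and logged,
not fatal. Wall-clock training times are recorded per cell as information
only.

Conditions are compared with a Kruskal–Wallis test per metric; the post hoc
is a Tukey–Kramer-style comparison of mean ranks with studentized-range
critical values at infinite degrees of freedom (the classic pairing for a
rank-based omnibus; the exact post hoc pairing is a design choice and is
flagged as such). All-identical inputs return p = 1 with a degenerate flag.

## Synthetic cohort generator

The generator emulates exactly the statistical structure the analysis
assumes, not biomechanics:

* gait classes are sums of a fundamental (clipped to 1.5–2.5 Hz) plus two
  harmonics with class-specific amplitude ratios per axis; stair classes
  differ from level walking by cadence within the band and harmonic ratios,
  not by leaving the band;
* driving is low-amplitude band-limited noise: a 0.3 Hz drift component
  plus wideband noise an order of magnitude weaker than gait;
* a constant 1 g offset on the y axis emulates gravity (exercising the
  DC-sensitivity decisions in the features);
* every activity boundary carries an explicit 2-s `transition` segment so
  the exclusion rule is exercised;
* per-subject variability is a multiplicative jitter (relative sd
  `subject_variability`) on amplitudes, fundamentals (re-clipped to the
  band) and noise levels;
* everything derives from a single seed via spawned `SeedSequence`s —
  cohorts are bit-identical under a fixed seed.

Reference study conditions (the `CohortSpec` defaults): 8 subjects × 360 s,
class shares {driving 0.64, walking 0.27, each stair class 0.045}, gait
noise sd 0.10 g, driving noise sd 0.02 g, subject variability 0.08. The
source corpus publishes no per-activity amplitude statistics, so amplitudes
are free parameters chosen to look like adult gait in g units; the
variability level was chosen so that an ankle-like cohort lands in the
regime reported for ankle sensors on real data (balanced accuracy ≈
0.9–1.0 under subject-wise CV, undersampling neutral to helpful). Schedules
split walking into three bouts and each stair class into two, mirroring
repeated short stair/walk trials, with driving last; shares are realized
exactly up to sample rounding (transitions excluded from the share
accounting).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: device noise spectra and calibration error,
desynchronization, gait asymmetry and stride-to-stride variability,
arm-swing decoupling at the wrist, posture changes within an activity, or
any amplitude calibration to the source corpus. Tests on this cohort
validate the pipeline's mechanics and the *direction* of balancing effects,
not real-data accuracy levels.

## Problem sizes used in the test suite

Pipeline-level tests run the full 8-subject × 360-s cohort (~2,600 epochs,
~190 k feature values) once as a shared fixture, and a 4-subject × 240-s
cohort whose class signal is confined to the y axis for the
importance-recovery check. Nonlinear-feature oracles use 200 series of
length 500 (Hurst), 2,000 steps of the logistic map (Lyapunov), and
500-sample sines and noise. The acceptance script reruns the Hurst oracle at
the same size from the supplied seed.

## Known limitations

* Whether undersampling helps is regime-dependent at desk scale: with ~100
  minority epochs, discarding 90% of the majority rows costs more than the
  prior-bias removal gains once class overlap or subject variability grows
  (observed at gait noise sd ≥ 0.12 with variability ≥ 0.12). The reference
  conditions sit in the regime where the imbalance correction wins, matching
  the well-separated-sensor setting; the package reports both arms so either
  outcome is visible.
* The R/S Hurst estimator is biased upward (~+0.06) at epoch length 500;
  comparisons between epochs are unaffected, absolute values should not be
  over-read.
* The Lyapunov estimator's fixed fitting horizon trades variance for a mild
  underestimate on slowly diverging signals; it is a feature, not a
  dynamical-systems measurement.
* Importance scores are impurity-based and inherit the known bias toward
  high-cardinality/continuous features; all 75 features here are continuous,
  so the within-set ranking is comparable.
* The MLP and SMOTE introduce the only non-seeded-library randomness;
  both are seeded through the spec/seed arguments, and experiment cells
  derive their seeds from the experiment seed, so full runs are
  reproducible.
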