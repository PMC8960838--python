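# Methods

`evlock` analyses the *temporal structure* of event-related BOLD responses
in parcellated fMRI data: when, not just whether, the mean response of a
brain region differs between two trial types.  This note describes the
model behind each stage, the parameters that matter, what the synthetic
generator does and does not emulate, and the numerical choices made where
the design was open.

## Event-locked mean signals

Each session's channel signals are demeaned and scaled to unit SD, averaged
into regions, and each region is divided by its SD over the concatenation
of all subjects and sessions (so regions of different size are comparable).
For every retrieval event, 12 frames are extracted — 2 before and 10 after
the event frame — and averaged over all trials of a class, giving 12 knots
at integer TR offsets −2..9 per region and class.  An event is locked to
the TR frame containing its onset (floor convention); sub-TR jitter is
deliberately ignored.  A *natural cubic interpolating spline* through the
knots is the continuous signal used everywhere downstream.  An
interpolating (not smoothing) spline is used so the curve passes through
the mean values exactly; natural boundary conditions avoid spurious
end-interval curvature.

The preparation order — normalize within session → parcellate → standardize
across the dataset → extract windows — is fixed; the first two steps do not
commute because z-scoring changes the relative weight of channels inside a
region.

## Observables

For a region's pair of curves `y_A, y_B` on a window `[T_i, T_f]`:

* **ΔArea** `= 1/(T_f−T_i) ∫ |y_A−y_B| dt`, by trapezoid quadrature on a
  1 mTR grid.  Windows: early `T_i=0, T_f=5`; late `T_i=5, T_f=9` (in TR
  after the event).
* **Edge delays.**  The rising edge of each curve is replaced by the chord
  from the preceding minimum `(t_0,y_0)` to the in-window maximum
  `(t_1,y_1)`; parametrizing chords by signal level `y` over the common
  range `[y_−, y_+]` (`y_− = max(y_0^A, y_0^B)`, `y_+ = min(y_1^A, y_1^B)`)
  gives the level-averaged delay `⟨Δt⟩`, its spread `σ` (zero iff the two
  edges are parallel), and the overlap fraction `range ∈ [0,1]`.  The
  trailing (falling-edge) statistics mirror this with chords from the
  maximum to the following minimum.  Because the chord difference is linear
  in `y`, the moments are evaluated in closed form
  (`⟨Δt⟩ = α + β(y_−+y_+)/2`, `σ = |β|(y_+−y_−)/√12`); a numeric-quadrature
  implementation is kept in the test suite as the oracle.  Sign convention:
  positive delay means the second-named class lags the first-named one.

Peak-search windows are configuration, not constants: the early screen
requires a local maximum of both curves in 1–5 TR while the early area
window starts at 0 — both values are carried separately in the run config.

### Numerical choices for anchors

Extrema are localized on a 1 mTR grid with parabolic refinement; flat
plateaus are kept as intervals (a rising chord anchors at the left plateau
edge, a falling chord at the right one), with ties reported leftmost.  When
several in-window maxima exist, the largest peak anchors the chord.  Two
robustness measures matter in practice:

* the walk from a peak to its adjacent minimum ignores dips whose back-rise
  is below 5% of the descended height — sampling noise on a slope does not
  qualify as "the minimum";
* each sharp anchor is refined to the vertex of a least-squares parabola
  fitted to the interpolant over ±1 knot spacing.  The fit is equivariant
  under time shifts of the curve, so shift recovery is unbiased, while
  noise in flat basins is averaged out.  Without this refinement the
  position of a minimum inside a nearly flat basin is dominated by noise
  and the delay estimator's spread roughly doubles.

If no minimum exists before the domain boundary, the boundary point is used
and the chord is flagged.  Chords shorter than 1e−6 in height are rejected;
chord pairs with disjoint level spans yield an undefined delay with
`range = 0`.

## Inference and region selection

*Multiple comparisons.*  A max-statistic permutation test: event labels of
the pooled trial collection are globally shuffled (no within-subject
stratification), per-region ΔArea recomputed through the full
mean→spline→area pipeline, and the maximum over regions recorded; the
0.95 nearest-rank quantile of 1000 such maxima is the family-wise critical
value.  The permutation maximum runs over all size-eligible regions, which
is conservative relative to restricting it to window-conforming regions.

*Errors.*  A label-preserving bootstrap: N trials drawn with replacement
from the pooled collection (N = pooled count), the observable recomputed,
and its SD over 1000 resamples taken as the statistical error;
`z = point estimate / bootstrap SD`.  The alternative numerator (bootstrap
mean) is computed and stored alongside.  Resamples on which the observable
is undefined are counted and excluded; more than 50% of them is an error.

*Selection.*  A region enters the delay tables iff (1) ΔArea exceeds the
permutation critical value, (2) `z(⟨Δt⟩) > 2`, (3) `σ < 0.15` TR, and
(4) `range > 0.1`; regions with fewer than 10 member channels are excluded
up front.  For each stage the pipeline evaluates both edges of the
in-window peak — its rising side (leading table) and its falling side
(trailing table) — under the same four criteria.

## Decoding

Per-TR decoding trains an independent classifier on region activations at
each offset 0..9; windowed decoding uses the full region×offset matrix
(718 × 10 = 7180 columns at the default parcellation size, region-major
column order).  Evaluation is stratified 5-fold cross-validation of the
ROC AUC; standardization and class balancing (random undersampling of the
training majority) are fitted inside each training fold only.
Hyperparameters (`C ∈ {0.01,…,1000}`, `gamma ∈ {1e−4,…,1}`) are selected by
a nested grid search within each training fold by default; a fixed-default
mode exists for speed.  Registered models: logistic regression, linear and
RBF SVM, an MLP (1–3 ReLU layers, 128/64/32 truncated to depth, sigmoid
output trained on binary cross-entropy, early stopping on a validation
split), and LightGBM gradient-boosted trees (grid: depth {4,6,8}, learning
rate {0.03, 0.1}, ≤500 trees; a fixed tree budget replaces early stopping
inside cross-validation).

## Shapley attribution

The attribution model is a LightGBM classifier fit on the (balanced) full
trial set.  Contributions are computed per trial and feature:

* **tree-exact** — LightGBM's native TreeSHAP in double precision.  The
  value function is path-dependent: features outside a coalition are
  marginalized down each tree with training-cover weights.  Efficiency
  (row sums equal margin output minus base value) holds to ~1e−14, and the
  values match an exhaustive 2^M coalition enumeration on the dumped trees
  to ~1e−14 for toy models.
* **sampling** — model-agnostic permutation sampling against a background
  sample (absent features take a random background trial's values), one
  telescoping walk per permutation so efficiency is exact per draw.  An
  exhaustive interventional brute force (≤12 features) is the oracle for
  this path.

The two paths use different value-function conventions on purpose: each is
checked against its own exact enumeration.

Features are ranked by `E(|φ_j|)` over all trials (train and test pooled);
pruning keeps the top fraction (default 15%) and retrains under the same
cross-validation protocol.  Aggregations: per-TR stacked weights (mean |φ|
grouped by region and offset, optionally normalized to sum to one; signed
sums are also available) and per-region sums over the early (0–4) and late
(5–9) TR windows, paired with ΔArea and the in-window-maxima flag for the
consistency scatter.

## The synthetic generator

The generator emulates a rapid event-related recognition-memory experiment
with four response classes and the study-scale defaults: TR 1.8 s; trial
totals 2159 / 903 / 1060 / 1747 (POScorr / LURfalse / NEGcorr / LURcorr)
split over 65 subjects × 2 sessions; inter-trial intervals from a truncated
exponential shifted to 6 s, capped at 15 s and scaled to mean 8.403 s (the
second inter-stimulus interval, mean 6.097 s in [2,16] s, is modelled the
same way); 718 regions.  Each region/class has a noise-free response
template: a double-gamma canonical HRF (peak 6 s, undershoot 16 s, ratio
1/6, unit peak amplitude) with configurable amplitude, whole-response onset
shift, and a trailing shift that delays only the falling edge (a time warp
pivoted at the HRF maximum).  Optional Gaussian components add a late
(5–9 TR) bump or a brief pre-peak initial dip.  Session signals are sums of
event-locked template responses plus AR(1) noise (coefficient 0.3,
innovation SD 1.0 by default) and a lognormal per-subject amplitude factor
(σ = 0.1, ≈±10%).  Ground truth is stored with every dataset.

Two fast paths bypass the session machinery for calibration studies:
`sample_trials` draws event-locked windows directly (window = class mean +
AR(1) noise) and `sample_null_trials` produces label-exchangeable noise.

### What the generator does not emulate — and what that implies

* **Overlap bias.**  With the task's real mean ITI (8.4 s ≈ 4.7 TR),
  neighbouring trials bleed into the 12-frame window.  The bleed is
  class-independent in expectation but *additive*, and an additive shared
  background breaks the pure-shift structure between two classes: injected
  delays measured through fully overlapping sessions are attenuated by
  roughly half.  This is a property of the event-locked-mean method itself,
  not of the implementation.  Recovery experiments therefore use wide trial
  spacing (ITI 36 s) or the direct window sampler; results on real,
  overlapping designs measure the attenuated effective delay.
* **Baseline structure.**  A template that is exactly zero before the rise
  has no identifiable preceding minimum, and no minimum detector can locate
  one stably under noise.  Recovery fixtures use a template with a −0.15
  initial dip (relative to unit peak), in line with the brief initial dip
  of measured BOLD responses; real data additionally has baseline structure
  from preceding trials.
* No spatial structure (regions are independent), no physiological noise
  (cardiac/respiratory), no motion, no grayordinate-level detail, and no
  behavioural response-time coupling.  Passing recovery suites therefore
  demonstrate correctness of the estimators under the stated noise model,
  not robustness to every artifact of real acquisitions.

## Problem sizes used in the validation suites

The statistical suites run at deliberately chosen sizes: delay recovery and
bootstrap behaviour at the study's pooled pair counts (2159 vs 903 trials,
50 replicates); permutation calibration at 50 regions, 200 trials per
class, 200 permutations and 200 replicates; decoding localization at 20
regions with 400 trials per class over 50 seeds; pruning retention on the
full 7180-column grid with 5% informative columns at amplitude 0.5 z-units
over 20 seeds.  `scripts/acceptance.py` repeats these measurements at
similar sizes from a user-supplied seed.

## Known limitations

* The delay observables assume a single dominant peak per window; multi-
  modal responses are resolved by the largest-peak rule, which may switch
  peaks between bootstrap resamples of borderline regions (such resamples
  typically fail the σ and range criteria).
* Amplitude-only contrasts produce nonzero level-parametrized delays by
  construction (a smaller response reaches each level later); the σ and
  range criteria are the guard against reading these as timing effects.
* The permutation test assumes exchangeability of trials across subjects
  under the null; within-subject correlation structure is not preserved by
  the global shuffle.
* `z` from 1000 bootstrap resamples is a Wald-style ratio; no bias
  correction or percentile interval is attempted.
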