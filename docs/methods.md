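# Methods

## Setting and model

`fairmove` targets score-emitting binary classifiers on tabular cohorts
with a rare outcome and named sociodemographic attributes. Every analysis
partitions one attribute into two groups (a, b); records outside the
partition — the "unknown" sentinel for marital status and working
condition, the "other" race category — are retained in the cohort and in
model training but excluded from that attribute's two-group analysis.

A classification at threshold `th` (a percentage) labels a record positive
iff `score × 100 ≥ th`, so `th = 0` labels everything positive — the start
of the mitigation search grid — and all metrics below follow from the
resulting confusion counts. Rates are computed on proportions internally
and scaled to percentages only when reported; reported cells round half
away from zero to two decimals.

## Equalized odds and the disparity Z

Equality of odds requires the predictor's true-positive rate (recall) and
false-positive rate (1 − specificity) to be independent of group
membership. The working objective is the sum of absolute between-group
gaps,

    Z(th) = |recall_a − recall_b| + |specificity_a − specificity_b|   [pp],

which is zero exactly at equalized odds, symmetric in the groups, and
non-negative. Z is always computed from unrounded group metrics.

## The constrained threshold search

The mitigation routine evaluates Z on the inclusive grid
{0, step, …, 100} (step 0.1 by default, 1001 points) and returns the
feasible minimizer. Feasibility is assessed on the *whole* analyzed test
set — overall recall ≥ `min_recall` (default 0.70) and overall accuracy ≥
`min_accuracy` (default 0.50), both inclusive comparisons — not per
group, so a single group's recall may legitimately end below the floor.
Ties in Z break toward the lowest threshold (first grid index). When no
grid point is feasible the search raises, attaching the full
(threshold, Z, recall, accuracy, feasible) trace so callers can inspect or
relax; a silent fallback would hide a binding constraint. Relaxing either
floor can only enlarge the feasible set, so the constrained minimum is
monotone under relaxation — a property the tests exercise.

The implementation counts true/false positives for all grid thresholds at
once from a sorted-score cumulative sum; the test suite pins it to an
independently coded exhaustive per-threshold rescan on random instances.

Bias improvement is reported as `max(z_default − z_mitigated, 0)`:
a constrained optimum that fails to undercut the default-threshold
disparity reports 0.00 rather than a negative improvement.

## Weighted majority voting

Per-attribute optimal thresholds are combined by weighted voting. For one
individual with score s, each attribute i casts `pc_i = 1[s×100 ≥ th_i]`,
and

    P = Σ_i w_i · pc_i,   class = 1[P ≥ decision_cut],

with `decision_cut = 0.5` — the natural weighted-majority rule; the cut is
configurable. Weights are disparity shares at the *default* 50% threshold,
`w_i = Z_i(50)/Σ_j Z_j(50)`: attributes whose groups are treated most
unevenly by the unmodified model carry the most repair weight. Weights are
stored unrounded, sum to one, and may be overridden by the user (overrides
renormalize); all attributes' thresholds apply to every individual — the
vote never conditions on the individual's own group memberships. All-zero
disparities leave the weights undefined and raise.

Consequences worth knowing: the vote is monotone in the score (raising a
score can never flip the class from 1 to 0), reduces exactly to
single-threshold classification when all thresholds agree, and projects
onto one attribute's rule when that attribute holds all the weight.

## AUC-based bias audits

*Algorithmic bias* is a between-group gap in ROC AUC for one fitted model
on one fixed test set, reported alongside group confusion metrics, Z, and
(optionally) a class-stratified permutation p-value for Z: group labels
are permuted within each outcome class, and the p-value is the smoothed
proportion of permutations with Z at least the observed value. The
permutation test is a deliberate, swappable choice; it makes no
distributional assumption about the paired rate differences.

*Sampling bias* is sensitivity of model quality to training composition:
for group-A fractions 0, 0.1, …, 1.0 a fresh model is trained on a
fixed-size sample with that composition and scored on a fixed, balanced
test set (per-group sizes default to half the published totals: sex 2992,
marital 2824, working 2648, race 640, income 1000). An AUC range above the
tolerance (default 0.05) flags the attribute. The grid, tolerance, sizes
and replicate seed are all configurable; "significant fluctuation" is a
judgment call in visual form, and the range-over-tolerance rule is its
operational stand-in.

## 1-N matching

Propensity scores come from an (effectively unpenalized) logistic model of
the outcome on the matching covariates — BMI plus the five attributes,
categorical attributes expanded to level indicators; columns are scaled
for optimizer conditioning only. Each case takes its n nearest controls by
absolute distance on the propensity logit, with replacement (at a
control:case pool ratio near n, matching without replacement is
arithmetically impossible) and no caliper by default; both are
configurable, controls never repeat within a case, and ties break by a
seed-deterministic jitter. When n is unspecified it defaults to
`round(n_controls/n_cases)` — 158 at the motivating survey's 157.6:1
ratio.

Balance diagnostics per expanded covariate:

    SMD = (mean_case − mean_control) / sqrt((var_case + var_control)/2)
    variance ratio = var_case / var_control

with the n−1 sample variance for continuous covariates and p(1−p) for
binary indicators. SMD is antisymmetric under role swap and the ratio
inverts; |SMD| < 0.1 and ratio ≈ 1 are the conventional balance calls. A
zero control variance leaves the ratio NaN rather than inventing a value.

## Risk models

Five families, all emitting scores in [0,1]:

- **nn_sgd / nn_adam** — a feed-forward network (two hidden layers of
  1000 rectified-linear units by default, sigmoid output) trained for 20
  epochs, batch size 64, learning rate 0.001, on weighted binary
  cross-entropy with balanced class weights `n/(2·n_class)`. Implemented
  directly on numpy; weight initialization (He) and the per-epoch
  minibatch shuffle derive from the run seed, so a retrain with the same
  (seed, config) reproduces scores bit-for-bit. Hidden activation and
  initialization are this package's choices — standard ones for this loss.
  Plain SGD at these settings converges slowly (that slowness is visible
  in its weak default-threshold recall); tests that need a converged SGD
  network use a higher learning rate and more epochs on smaller layers.
- **logistic** — scikit-learn, balanced class weights, C = 1.
- **svm_linear / svm_rbf** — C = 1, balanced class weights, with Platt
  sigmoid calibration on training folds to produce probabilities; the RBF
  kernel width follows γ = 1/(n_features · feature variance) (the "scale"
  convention).

BMI — the only continuous input — is z-scored inside the model pipeline
for kernel and gradient conditioning; the 44 binary predictors pass
through unchanged. The scaling is recorded in the fitted pipeline and
travels with the saved model bundle together with a feature-schema
fingerprint, so scoring a mismatched cohort fails loudly.

## The synthetic cohort generator

The generator emulates a large household-survey cohort: 32,893 records,
0.63% outcome prevalence, five attributes with the survey's marginal
composition, BMI ~ N(25.59, 8.82²) clipped to [12, 70], and 44 binary
predictors — 29 clinical indicators (opioid-type use, heroin, treatment
history, comorbidities, other substance use) with fixed prevalences and
log-odds coefficients recorded in the packaged schema, plus 15 one-hot
attribute levels derived from the attribute columns. Outcomes are drawn
from a logistic model over these predictors with Gaussian latent noise
(sd 1.0); the intercept is calibrated by root finding so the expected
outcome rate equals the configured prevalence. The clinical coefficients
were set once so that a cohort-scale logistic model reaches a test ROC AUC
near 0.9, the discrimination band typical of this prediction task.

Bias is injected per attribute, applied to the first analysis group:

- **outcome** bias adds a log-odds shift — label bias: the group's
  prevalence differs at identical covariates. This is what propensity
  matching and threshold mitigation should (and in the simulations do)
  detect and repair.
- **signal** bias shifts the log-gain of the predictor-driven signal:
  members of the group get linear predictor `exp(s)·(Xβ)` before noise.
  Gain ≠ 1 changes how strongly the group's outcomes track its observed
  predictors, so fitted models discriminate unevenly across groups
  (algorithmic bias as an AUC gap) and models trained on one group
  transfer poorly to the other (sampling bias in the composition sweep).
  After applying the gain, each gain-stratum's intercept is re-calibrated
  to its gain-free prevalence, so signal bias changes discriminability
  without starving a group of cases — prevalence differences remain the
  outcome shift's job.

What the generator does *not* emulate: survey weights, item missingness
beyond the sentinel categories, correlations between clinical predictors,
age structure, or multi-group attribute effects. Passing simulation
checks therefore demonstrate that the machinery recovers and repairs bias
of the kinds injected, under clean marginals — not that any particular
real survey is biased.

## Problem sizes in tests and the acceptance script

Simulation studies run at sizes chosen to make their conclusions stable:
mitigation recovery at n = 5000 over 10 seeds (logistic scorer, outcome
bias +1.0 and signal +0.5 on sex, prevalence 0.1 so group confusion cells
are well filled); the sampling-bias flag contrast at n = 30,000 with
training size 4000 per composition (retrain variance, not test noise,
dominates the null sweep's AUC range — 4000 keeps the unbiased
attribute's range near 0.03, comfortably under the 0.05 tolerance, across
seeds); matching balance at n = 3000 with n = 10 controls per case over
10 seeds. The worked-example checks recompute published summary cells
from published row inputs and run in well under a second.

## Numerical conventions and edge cases

- Thresholds compare with ≥ on the percent scale; grid endpoints are
  inclusive.
- Metrics with zero denominators are `None` ("undefined"), never 0; the
  disparity and the search refuse degenerate groups explicitly.
- Bootstrap intervals are percentile intervals over class-stratified
  resamples; a resample on which the metric is undefined is redrawn and
  counted.
- All randomness flows through explicit integer seeds; there is no global
  random state anywhere in the package.

## Known limitations

- Two groups per attribute; multi-group attributes must be dichotomized
  (the race analysis contrasts White and Black, excluding other groups).
- One threshold per attribute; no single threshold jointly optimal across
  attributes is attempted.
- The permutation p-value is a design stand-in for an unspecified test;
  its null is exchangeability of group labels within outcome class.
- WMV weights are fixed disparity shares, not learned; the decision cut
  is a convention.
- The numpy network is deliberately small-scale (CPU, two hidden layers);
  it is not a general deep-learning component.
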