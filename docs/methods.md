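# Methods

## Evidence scale

The ACMG/AMP point framework treats evidence as additive integer points whose
likelihood ratios combine multiplicatively. `vepcal` makes the whole scale a
pure function of the prior probability of pathogenicity α: the very-strong
odds constant *C* is solved numerically (Brent root bracketing on log *C*
over [1, 10¹²]) so that a variant carrying the minimal Pathogenic point total
(10 points by default) reaches a posterior of 0.99. Point-level thresholds
then scale exponentially, LRₓ = C^(x/8), so LR₊₂ = LR₊₁² and LR₋ₓ = 1/LR₊ₓ by
construction. Continuous evidence points are EP(s) = Clip(log LR(s) / log
LR₁, EPmin, EPmax) with clip bounds ±8 rather than the clinically usable ±4:
a calibration that claims +7 where the truth is +5 is an error of two points,
which ±4 clipping would hide. Integer points truncate toward zero, so a
variant must meet or exceed a threshold to earn the point — the conservative
direction. Both the pathogenic point total (10) and the target posterior
(0.99) are arguments of `build_evidence_scale`; an alternative convention
that solves several tier constraints simultaneously can be emulated by
changing them. Posteriors are clamped to [1e−9, 1 − 1e−9] before odds
conversion.

Point-sum tiers follow the published point-based system: Pathogenic ≥ 10,
Likely pathogenic 6–9, VUS 0–5, Likely benign −6…−1, Benign ≤ −7.

## Calibration methods

Eleven score-to-posterior maps are implemented. Platt and weighted Platt
(inverse class-frequency weights) are near-unregularized logistic fits. Beta
calibration is the three-parameter logistic fit on (ln s, −ln(1 − s));
negative shape coefficients would break monotonicity, so a negative
coefficient drops its feature and the model is refit, the standard reduction
to the monotone sub-family. The three mixture methods fit one density per
class by maximum likelihood — skew-normal, beta, or [0, 1]-truncated normal —
and combine them through Bayes' rule at the training pathogenic fraction α′.
Isotonic regression is pool-adjacent-violators; smoothed isotonic passes a
monotone piecewise-cubic Hermite interpolant through the midpoints of the
isotonic steps; the spline method fits a cubic smoothing spline to the logit
of an isotonic pre-fit with the smoothing factor chosen by 5-fold
cross-validated log-loss over a small grid. The monotone network is a
1→16→16→1 MLP whose weights are softplus-re-parameterized (hence
non-negative, hence a monotone map), trained full-batch with Adam on the
binomial negative log-likelihood with a 20% validation split and early
stopping; initialization is seed-fixed. The local posterior estimator —
the method underlying genome-wide calibration — expands a symmetric window at
each evaluation score until it holds a required fraction of labeled scores
(10/20/30%) and optionally of unlabeled population scores (0/3/6%), then
weighs the window's class fractions by the target prior. The nine
(window × unlabeled) configurations compete in selection as nine distinct
candidates.

A mixture calibrator's posterior is the ratio of fitted tail densities, which
can behave erratically outside the observed score range (e.g. a skew-normal
ratio exploding at score 0). The selection stages penalize such methods when
the artifact reaches the simulated score range; it is a known residual
limitation for scores far outside the control support.

All fitted maps reflect their training pathogenic fraction α′. When a unit's
deployment prior α differs, `prior_shift_correct` converts the posterior to a
likelihood ratio at α′ and re-applies Bayes' rule at α; the correction is
exact for a correctly calibrated input and order-preserving always.

Methods that fail to fit (optimizer divergence, too few distinct scores)
raise a fit-failure signal and are excluded from selection for that unit;
nothing downstream crashes.

## Synthetic score engine

Class-conditional score distributions are modeled with four families on
[0, 1]: Beta, truncated Normal, truncated Skew-t, and truncated Skew-Cauchy.
The skew-t is the Azzalini form (location, scale, skew, df) built from the
Student-t density and CDF; skew-Cauchy is its df = 1 analogue. Truncated
densities are renormalized by the numeric mass on [0, 1] (trapezoid
quadrature, 4001 points; 513 during optimization). Sampling uses inverse-CDF
interpolation on the same grid, uniform across families; the discretization
error is far below sampling noise at the sizes used. Family fitting is
maximum likelihood (closed-form-free families via Nelder-Mead on transformed
parameters); the best family is the one with the highest log-likelihood,
ties broken by the fixed family order.

The scenario grid is the Cartesian product of calibration sizes
{25, 50, 100, 300, 500, 1000}, observed pathogenic fractions
{0.05, 0.1, 0.2, …, 0.9, 0.95}, and true priors {0.01–0.1 by 0.01, 0.2, 0.3,
0.4, 0.5} — 924 scenarios per distribution pair. Class counts are
deterministic, round(n·α′), for reproducibility; test sets (1000 draws by
default) come from the α-weighted mixture and carry closed-form true
posteriors and true evidence points.

What the generator does not emulate: score discreteness and heaping of real
predictors, annotation errors in control labels, correlated variants within
a gene, and transcript-mapping noise. Passing tests therefore establish the
statistical machinery under clean, well-specified conditions, not the
robustness of a particular predictor's real-world calibration.

## Miscalibration metrics

ΔEP(s) = EP_est(s) − EP_true(s) in continuous points under ±8 clipping. MAPE
is mean |ΔEP|; PFraction is the share of test scores with ΔEP > 1 among those
in the pathogenic region, BFraction the mirror image. The literal region
definitions (EP_true > 1 / < −1) are the default; a `strict_regions=False`
switch gives the ≥ 1 / ≤ −1 reading — the two differ only on the boundary
set. Region-wise 75th-percentile and maximum errors use +ΔEP in the
pathogenic region and −ΔEP in the benign region, the overconfidence
directions.

## Data-adaptive selection

Eligibility is tiered: 50–99 labeled variants require a balanced class mix
(0.4 ≤ pfrac ≤ 0.7); 100–299 allow 0.1–0.9; ≥ 300 allow 0.05–0.99 with at
least 10 benign controls. The size ranges are disjoint, so conditions
partition.

For an eligible unit, replicate synthetic sets are generated from the
best-fitting family pair at the unit's own n and α′ and evaluated at the
unit's prior. Stage 1 removes any method whose replicates violate the tail
safety rule (75th-percentile regional overconfidence error > 2 points or
maximum > 3 points, in either region) in more than 25% of replicates. Stage 2
keeps the three survivors with the lowest mean per-replicate MAPE rank;
stage 3 picks the finalist with the lowest mean rank of
PFraction + BFraction. Rank ties break alphabetically, making selection
deterministic. The full protocol uses 30 replicates and the conservative
out-of-bag posterior in stage metrics; the package defaults are 10
replicates scoring each method's plain fit (`stage_posterior="point"`),
which keeps a desk-scale unit under ~5 s while preserving the ordering in
every case examined — the conservative variant is one config switch away.

The chosen method is refit on the real unit under a 1000-round (configurable)
out-of-bag bootstrap: per-score 5th/95th percentile estimates bound the
posterior, and the conservative curve substitutes the 5th percentile wherever
the full-data fit implies ≥ +1 point and the 95th wherever it implies ≤ −1.
Evidence score intervals are read off the conservative curve on a 1001-point
grid.

## Prior estimation

The positive-unlabeled prior estimator contrasts labeled pathogenic variants
with unlabeled population variants in feature space. Ensemble members train
on unique-bootstrap samples — a variant present in both sets always has both
copies on the same side of the split — balanced by random under-sampling,
z-scored and PCA-projected to 95% cumulative explained variance using
training-sample statistics only, with an L2-regularized logistic learner (the
learner is interchangeable; logistic is fast and deterministic). Out-of-bag
averaging yields unbiased per-variant scores. The distance curve removes the
closest unlabeled variant to a randomly drawn positive, once per unlabeled
variant; the number of unlabeled positives is the elbow of the curve, located
as the breakpoint of a two-segment piecewise-linear least-squares fit to the
cumulative curve (O(n) via prefix sums). This deterministic elbow detector
replaces a pretrained meta-model and is validated by parameter-recovery
simulation (median error ≤ 0.07 at mixture proportions 0.05–0.5). Degenerate
curves are flagged: no slope increase with uniformly large distances gives
prior 0 ("flat"); uniformly tiny distances give prior 1. The final estimate
is the median over 5000 bootstrap curves (200 in fast test mode) with the
interquartile range as uncertainty, retained only when the PU-AUC exceeds
0.75 — below that, positives and unlabeled variants are not separable enough
for the removal process to be informative.

## Domain clustering

Domain intervals within a gene are made non-overlapping first: reciprocal
overlap ≥ 50% of both intervals merges them, smaller overlaps split at the
overlap midpoint, applied pairwise left-to-right until stable. Each domain's
all-SNV score distribution is a 100-bin histogram with pseudocount 1e−6;
similarity is the Jensen–Shannon distance (square root of base-2 JS
divergence — a bounded metric). Average linkage builds the dendrogram
(configurable); the dynamic cut descends from the root, splitting any branch
whose member domains exceed the labeled-count cap, so cluster granularity
follows control-variant density rather than a fixed k. The cap is chosen by
grid search (50 log-spaced candidates) to put the median per-cluster labeled
count closest to 500 — enough controls to calibrate most clusters while
keeping shapes homogeneous. Cluster validation fits an unsupervised
two-component skew-normal mixture (EM with weighted Nelder-Mead M-steps,
seeded restarts, components ordered by mean) to a cluster's all-variant
scores and compares each component against cluster-level versus genome-wide
control histograms by JSD; a positive difference means the cluster's own
controls resemble the mixture components more closely.

Variants outside any resolved domain form a single non-domain pool; splitting
that pool further is out of scope.

## Numerical choices and limitations

- Evaluation grids are 1001 equispaced points on [0, 1].
- Bootstrap replicate b of a run with seed s uses the deterministic child
  seed (s, b); every stochastic routine takes an explicit seed.
- Interval membership is closed on both ends; interval LRs with zero benign
  controls report +∞ and count as maximally conservative in win comparisons.
- Win rules: both-on-side → closest to the threshold in log-LR; split →
  the conservative side; exact equality → tie. The binomial win test is the
  exact one-sided tail at p = 0.5 excluding ties.
- Problem sizes in the test suite and acceptance script (10 replicates,
  60–200 bootstrap rounds, 500-score test sets, 5-seed recovery medians) are
  the package's desk-scale defaults; the full-protocol values (30
  replicates, 1000 bootstrap rounds, 5000 prior bootstraps) are plain
  configuration arguments.
- The framework calibrates rank-preserving maps of a predictor's scores; it
  cannot repair a predictor whose ranking is poor in a gene or domain, and
  metrics computed against labeled controls inherit any circularity present
  in how those controls were classified.
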