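# Methods

## The estimation problem

The unit of observation is a HOLC-graded neighborhood polygon in a planar
CRS (meters).  Exposure is the number of wells whose Euclidean distance to
the polygon is ≤ 100 m (cumulative; a 0 m buffer gives the "fully
contained" sensitivity variant; density divides by the polygon's own area
in km², never the buffered area, so area statistics stay interpretable).
Wells are classified against the city's appraisal year at year
granularity: *undated* iff all four recorded years (spud, completion,
first/last production) are missing; *pre* iff any present year is strictly
earlier than the appraisal year; *post* otherwise.  Undated wells count in
the all-time analyses and are excluded from pre/post by construction.
A well on the shared boundary of two neighborhoods counts for both; each
neighborhood's buffer test is independent.

The causal question is asked pairwise between adjacent grades — A vs B,
B vs C, C vs D — with "treatment" A = 1 meaning the worse grade.  The
estimand is the average treatment effect on the well count over the
restricted-and-matched comparison population.  Because matching with
replacement reweights the better-graded arm toward the worse-graded arm's
covariate distribution, this population is close to the treated (worse
graded) units; with effect heterogeneity that quantity can exceed the
plain pair-population ATE, which is worth remembering when comparing
pipeline estimates to the generator's `true_ate` (an average over all pair
members).

## Areal apportionment

Census covariates live on tracts; neighborhoods and tracts are incongruent
polygon layers.  Extensive variables (population, homes) transfer as
Σₜ xₜ · |v∩t|/|t|; intensive variables (proportions, median home value,
people per home) as intersection-area-weighted means, with a
population-weighted option.  Median home value is apportioned as a weighted
mean of tract medians — a pooled median is not identifiable from
aggregates; this is the usual areal-interpolation compromise.  A
neighborhood whose tract coverage is below 0.5 (configurable) is excluded
from the matched analyses, the per-neighborhood analogue of restricting the
study to cities with digitized tract data.

## Propensity stack

Base learners: plain logistic regression, ridge-penalized logistic
regression (C = 1 on standardized covariates), and a cubic-spline additive
logistic model (4 knots per covariate, linear extrapolation).  The roster
preserves the function classes of the classic SuperLearner ensembles used
in this literature — linear, shrunken-linear, smooth-nonlinear — without
depending on legacy implementations.  Stacking weights live on the simplex
and minimize the pooled k-fold out-of-fold loss over an exhaustive grid at
0.01 resolution; the vertices are feasible, so the stacked CV risk can
never exceed the best single learner's.  Folds are fixed by the seed
(k = 10 by default).  Zero-variance covariates are dropped with a warning;
complete separation is survivable because the ridge learner stays finite.

Overlap restriction drops units with scores strictly below the 1st or
strictly above the 99th percentile of the pooled pair (per-arm percentiles
are a config switch; the linear-interpolation quantile definition is used
throughout).  Matching is 1:1 nearest-neighbor on the score with
replacement; ties break to the lexicographically smallest control id, and
control reuse counts are carried forward as frequency weights.

## TMLE

Continuous-outcome TMLE with the outcome scaled to [0,1] by the pooled
observed range (fixed bounds are a config option): initial outcome
regression Q̄⁰(A,W) by the stacked ensemble under squared-error loss;
treatment mechanism g(W) by the stacked propensity model truncated to
[0.01, 0.99]; fluctuation of logit Q̄⁰ along H(A,W) = A/g − (1−A)/(1−g) by
a no-intercept offset logistic regression solved with Newton iterations to
|Δε| < 1e-10; estimate ψ̂ = weighted mean of Q̄*(1,W) − Q̄*(0,W) rescaled;
standard error from the efficient influence curve, whose weighted mean is
zero after targeting (checked to 1e-8·sd).

Both nuisances are **cross-fitted** by default: each unit's Q̄ and g
predictions come from learners trained on the other CV folds, with
stacking weights chosen on the pooled out-of-fold loss.  In-sample
nuisance predictions (available via `TmleConfig(crossfit=False)`)
measurably understate the influence-curve variance on small cities
(~150 units, 10 covariates): null-effect interval coverage fell to
0.65–0.75 where the cross-fitted estimator is nominal.  Full CV-TMLE
(cross-validated targeting) is deliberately not implemented.

Matched data enter TMLE with control frequency weights in every
regression, the fluctuation and the influence-curve variance; an
unweighted mode (each matched unit once) is always emitted alongside.
**Limitation:** frequency weights treat a reused control as independent
replicates, which understates sampling variability under heavy reuse
(measured matched-null coverage ≈ 0.90 vs ≈ 0.95 for the unweighted mode).
Coverage checks in the test suite therefore use the unweighted matched
mode; both columns appear in `results.csv` so the discrepancy is visible
rather than silently resolved.

Degenerate cases: constant outcome returns a zero effect with zero SE and
a warning; a single-arm input or a weighted sample below 30 is an error.

## Synthetic cities

`CityConfig` defaults describe a mid-size oil town: a 10×10 grid of 1 km
square neighborhoods, base intensity 2 wells km⁻² for grade A, intensity
ratio 1.3 per grade step, confounder scale 0.8, half of the wells
pre-appraisal, 30% of wells undated — magnitudes chosen so that counts,
densities and date-missingness sit in the range reported for U.S. cities
with HOLC maps and wells (well densities of a few to ~12 km⁻², roughly
half of wells carrying dates).

The latent desirability field U is an iid Gaussian grid convolved with a
3×3 kernel (rescaled to sd `confounder_sd`) plus a north–south linear
trend of the same scale.  Smoothness is not cosmetic: tract covariates are
generated from *tract-averaged* U, so a spatially rough field would make
neighborhood-level confounding unobservable in principle and no estimator
could recover the ground truth.  Grades discretize −U into exact quartiles
after adding independent noise (sd 0.5), so grade is confounded with U but
not determined by it.  Well counts are Poisson with log-intensity
`base + step·grade_index − 0.5·U`: undesirable (low-U) land attracts both
wells and bad grades, so the naive grade contrast overstates the causal
one — the direction of confounding the matched analysis must overcome.
Tract covariates are linear in −Ū with independent noise and clipping,
their gradient signs matching the historical census gradients (median home
value and high-school completion fall A→D; Black, foreign-born and
non-White-employed proportions rise; radio ownership falls).  Pre wells
get years `appraisal − 1 − Geometric(0.25)` lag, post wells the mirror
image; all four year fields are erased together with probability
`frac_undated`.

Ground truth records U, each neighborhood's expected count under every
counterfactual grade, and `true_ate(pair, period)` — the mean
counterfactual difference over the pair population, thinned by the
period's date-retention fraction.

What the generator does **not** emulate: real HOLC polygon shapes and
street-following boundaries, spatial clustering of wells within fields,
within-city appraisal-date variation, measurement error in well
coordinates, and covariate dependence beyond a single latent factor.
Passing tests therefore demonstrate the statistical machinery is correct
under a known generative model, not that any historical estimate is
unbiased.

`simulate_matched_scenario` is the companion arm-level generator for
estimator calibration: Poisson outcomes `Y ~ Pois(exp(0.7 − 0.6Z) + τA)`
with `logit P(A=1) = −0.8Z` and the carrier Z observed (as a rescaled
median home value among ten named covariates), so the ATE is exactly the
designed τ for every unit and both nuisances are inside the learners'
function class.  It is used where the target must be known in closed form
(the city generator's multiplicative effects are heterogeneous).

## Simulation-study sizes and numerical choices

The recovery study uses 500 replicates at 400 units/arm with a designed
2.0-well effect; estimator-vs-naive dominance uses 200 replicates at 150
units/arm; pipeline null-coverage uses 200 twelve-by-twelve null cities;
the ANOVA type-I error uses 10,000 three-group null draws.  Monte-Carlo
studies run the stack with 5 folds (the default for single fits stays 10).
Boundary conventions: buffer inclusion is closed (distance ≤ buffer);
"before appraisal" is a strictly earlier year; percentile trimming uses
strict inequalities so tied scores are never dropped; probabilities are
clipped to [1e-12, 1−1e-12] before logits; g is truncated to [0.01, 0.99].
A single study seed fans out into per-stage seeds through
`numpy.random.SeedSequence.spawn`, making every run (and partial rerun)
bit-reproducible.
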