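# Methods

## The health transform

The response is a preference-based health utility score h bounded on
[0, 1] with strong negative skew (most adults report good health).  The
two-parameter families used here live on the positive half-line with
positive skew, so modelling happens on the reflected score

    h* = 1.0001 − h,       h* ∈ [0.0001, 1.0001].

The offset 1.0001 (rather than 1) keeps h* strictly positive at h = 1.
All model parameters, predictions and residuals are on the h* scale; the
risk module converts back, so a threshold t on health becomes the h*
survival probability at 1.0001 − t.

## Distribution families

All families are parameterized by a location μ and scale s:

* **gamma** — shape 1/s², scale s²μ, so E = μ, SD = s·μ (s is the CV).
  Density: f(x | μ, s) = x^{1/s²−1} exp(−x/(s²μ)) / ((s²μ)^{1/s²} Γ(1/s²)).
* **weibull3** (mean-parameterized Weibull) — shape k = s, scale
  λ = μ/Γ(1+1/k), so E = μ exactly and the CV depends only on the
  shape: CV² = Γ(1+2/k)/Γ(1+1/k)² − 1.  Moment inversion solves the CV
  map for k by bracketed Brent root-finding (xtol 1e-13), with the CV
  evaluated through log-gamma differences so small shapes do not
  overflow.
* **lognormal** — log X ~ N(μ, s²).  Here μ is on the log scale and is
  typically negative for h* ≈ 0.2; it therefore gets an identity link
  in the regression (the other two families use log links on both
  parameters).

pdf/cdf/quantile evaluation delegates to `scipy.stats`; the package owns
only the reparameterizations, moment maps, and their inversions.

## Distributional regression

Both parameters are regressed on the same 27-column design: log income
(in $1000 — since income enters only through its log, the unit choice
moves the intercept only), age, a squared age term centered at the
sample mean age, the two children counts, life satisfaction, and 20
dummies over seven categorical factors with fixed reference levels
(non-indigenous, service & sales, non-smoker, fairly good sleep,
sometimes time-stressed, neither weight-satisfied/dissatisfied, frequent
physical activity).

Estimation is plain maximum likelihood — the predictors are strictly
linear, so no smoothing penalty is involved — by alternating Newton
scoring: update β^μ holding β^s, then β^s holding β^μ, each with up to 5
inner Newton steps and step-halving (up to 30 halvings) so the deviance
never increases.  The outer loop stops when the deviance changes by less
than 1e-6 (default; cap 200 iterations, error with the trace attached on
non-convergence).  Per-observation scores and curvatures are analytic
for the gamma (expected information: weight 1/s² for the location block,
4d²ψ′(d) − 4d with d = 1/s² for the scale block) and the lognormal;
the Weibull block derivatives use central finite differences with step
1e-5 on the predictor scale, with curvature floored at 1e-10 to keep
the scoring direction well-defined.

Starting values: intercepts from moment-matching the marginal h*
(β₀^μ = log mean, β₀^s = log CV), slopes zero.

Standard errors come from the observed information of the joint
54-coefficient vector, assembled from per-observation numeric second
derivatives (including the μ–s cross term) and inverted once.  The
summary table stars coefficients at the 0.05/0.01 two-sided normal
levels.

Diagnostics: global deviance, AIC = deviance + 2p and
BIC = deviance + p·log n with p counting coefficients across both
predictors, and normalized quantile residuals
r_i = Φ⁻¹(F(h*_i | μ̂_i, ŝ_i)) — standard normal iff the assumed family
is right; the response is continuous, so no randomization is needed, and
CDF values are clamped to [1e-12, 1 − 1e-12].  Residual skewness and
kurtosis (non-excess) summarize the misfit; on gamma data the lognormal
family shows the largest AIC and residual skewness, with gamma and
Weibull close together.

## Quantile regression

For each τ the check-loss problem is solved exactly as the standard
primal LP (split residuals u, v ≥ 0; X β + u − v = h) with the HiGHS
solver.  Degenerate problems may have multiple minimizers; any global
minimizer is accepted, and invariants are asserted on the attained loss,
which is unique.  The Koenker–Machado-style goodness of fit is
1 − loss/loss₀ with loss₀ the best constant fit (the τ-th sample
quantile).  Grid defaults: the nine-point grid 0.1, …, 0.9 for
coefficient tables and the bridge, and τ = k/1000, k = 1..999 for the
non-parametric CDF.  Coefficient standard errors, when requested, come
from a pairs bootstrap (default B = 200) — a deliberate, labelled choice
among the several common options.

**Quantile crossing.**  Predicted quantiles need not be monotone in τ.
Before CDF inversion they are sorted (monotone rearrangement), which
preserves the set of predictions while restoring the monotonicity the
inversion requires; the crossing count is logged.  The empirical tail
probability at threshold t is then the largest τ whose rearranged
quantile is ≤ t (0 below the smallest), a step-function inverse that is
non-decreasing in t by construction.

## CDF matching (the parametric bridge)

Reflected predicted quantiles satisfy P(h* ≤ 1.0001 − ĥ^τ) = 1 − τ, so
the gamma parameters are chosen to minimize the equally weighted sum of
squared differences between these empirical CDF values and the
theoretical CDF.  The optimization runs unconstrained in
(log μ, log s) — positivity for free — started from moment-matching of
the K reflected quantiles, with Nelder–Mead (xatol 1e-10, fatol 1e-14)
followed by a BFGS polish; the result is rejected if it ends above the
starting objective.  Nine quantiles are enough: fits from 9 and 19
quantiles of the same distribution agree to ~1e-3 in both parameters,
and analytic-quantile inputs are recovered to 1e-4 relative.

## Risk measures, contrasts, bootstrap

The five measures per covariate profile are E(h), σ, and
P(h ≤ 0.8/0.7/0.6) ("average"/"fair"/"poor", roughly the 50th/30th/10th
percentiles of the score's marginal distribution).  Contrasts between
two profiles report absolute (a − b) and relative ((a − b)/a, %)
differences, computed from unrounded quantities — tables recomputed from
rounded cells can differ in the last digit.

Confidence intervals use the percentile bootstrap: individuals resampled
with replacement (no household clustering — resampling treats persons as
independent), the full pipeline re-run per replicate, and the 2.5th and
97.5th percentiles of the replicate values reported.  Default B = 1000,
configurable; all replicate streams derive from one master seed.  Failed
replicates are dropped and logged, with an error above a 10% failure
rate.  Percentile intervals can in principle exclude the point estimate;
this is logged, not "fixed".  Coverage for a sample mean at n = 80,
B = 200 is ≈93–95% across 200 simulation repetitions.

## The synthetic cohort

The generator emulates a large national household survey wave
(N = 14,728) whose person-level data are restricted.  Covariates are
drawn **independently** per variable from published marginals:

* income ($1000): lognormal matched to mean 51.13 / SD 34.92, floored
  at 0.1 (the published minimum is 0.00, and how zero incomes entered a
  log transform is not documented; the floor keeps log income finite and
  affects ~no draws), capped at 1781.22;
* age: rounded normal (44.87, 18.57) clipped to [15, 96]; life
  satisfaction: rounded normal (7.93, 1.41) clipped to [0, 10].
  Clipping slightly shifts means relative to the raw parameters; tests
  compare against the clipped-distribution mean;
* children counts: exact three-point pmfs on {0, 1, 2} matching both
  published moments (0.18/0.51 and 0.30/0.71) — a rounded normal cannot
  match both for a count variable with mean 0.18;
* categoricals: multinomial draws at the published shares.

Health is then drawn from the conditional gamma model with the published
coefficient estimates as generating values, with one deliberate
exception: the squared-age coefficient is printed as 0.000 (rounded
away), and the generator uses 0.0002 on both predictors so the
nonlinearity is exercised at all — this value is *not* a published
estimate.  The gamma's support exceeds [0.0001, 1.0001], so a draw can
imply h < 0; `truncate_support` rejects and redraws those (logged).  It
is **off** by default because truncation biases maximum-likelihood
recovery of the generating coefficients, and on only for realism
demonstrations.

What passing tests show, and what they do not: parameter recovery,
residual calibration and the agreement of the three estimation routes
are demonstrated under independent covariates and a correctly specified
family.  Real survey data have correlated covariates (income with
occupation, smoking with sleep), measurement error and clustering; none
of that is emulated, so the tests validate the estimators, not the
substantive published effect sizes, which are not reproducible without
the restricted data.

## Problem sizes and numerical defaults

Package-level test and demonstration sizes are chosen to keep each run
comfortable on a laptop: cohorts of 1,500–5,000 for unit tests, 20
cohorts of 15,000 for the recovery study (a fit takes well under a
second), dense quantile grids of 49–999 points depending on context, and
bootstrap studies at n = 80, B = 200.  The fitter's tolerances
(deviance 1e-6, probability-scale 1e-8 to 1e-10 for quantile/CDF
round-trips) are stated alongside each component above.

## Known limitations

* Associational only — no instruments, no endogeneity correction.
* No survey weights, no household clustering, no panel structure.
* Linear predictors only; no smooth/additive terms, no interactions.
* Two-parameter families only; no skewness/kurtosis predictors or
  mixtures.
* Independent-covariate synthetic data (see above).
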