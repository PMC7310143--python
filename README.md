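# healthdist

Distributional regression of income-related inequality in health.

Conventional regressions of a health score on income describe only the
conditional *mean* and therefore miss the question that matters for
health policy: does extra income shrink the risk of ending up in *bad*
health, and by how much?  `healthdist` implements the distributional
toolkit for that question on a bounded, negatively skewed health utility
score (an SF-6D-like index h in [0, 1]), aimed at health economists and
epidemiologists working with survey data.

## The models

The score is reflected to a positive, positively skewed variable
h\* = 1.0001 − h and analysed three ways:

**Location–scale distributional regression (GAMLSS-type).**  h\* given
covariates follows a two-parameter family — gamma (default),
mean-parameterized Weibull, or lognormal.  For the gamma with
E(h\*) = μ and SD(h\*) = s·μ, both parameters get their own linear
predictor through a log link:

    log μ_i = β₀^μ + β₁^μ log(income_i) + β₂^μ X_i
    log s_i = β₀^s + β₁^s log(income_i) + β₂^s X_i

fitted by maximum likelihood with alternating Newton scoring.  Model
comparison uses the global deviance (−2 log L), AIC, BIC and normalized
quantile residuals Φ⁻¹(F(h\*ᵢ | μ̂ᵢ, ŝᵢ)).

**Check-loss quantile regression.**  For each quantile level τ the
coefficients minimize Σᵢ ρ_τ(hᵢ − xᵢ'β) with
ρ_τ(u) = u(τ − 1{u<0}), solved exactly as a linear program.  A grid of
fits gives predicted conditional quantiles ĥ^τ(x); sorting them
(monotone rearrangement) yields a step-function estimate of the
conditional CDF of health.

**The parametric bridge.**  K predicted quantiles pin down K points of
the CDF of h\*: P(h\* ≤ 1.0001 − ĥ^τ) = 1 − τ.  A gamma distribution is
then estimated by least squares between empirical and theoretical CDF
values,

    min_{μ,s} Σ_k (1 − τ_k − F(1.0001 − ĥ^{τ_k}; μ, s))²,

which typically needs only nine quantiles for stable parameters.

All three routes end in the same five summary measures for a covariate
profile: E(h), σ, and the tail risks P_avg = P(h ≤ 0.8),
P_fair = P(h ≤ 0.7), P_poor = P(h ≤ 0.6), with 95% percentile-bootstrap
intervals.  Because the study-scale survey data (HILDA) are restricted,
the package ships a synthetic cohort generator that reproduces the
published covariate marginals and draws health scores from the
conditional gamma model, so the entire pipeline is testable end to end.

## Worked example

```python
import numpy as np
from healthdist import (CohortConfig, DistributionalRegression, QuantileRegression,
                        simulate_cohort, reference_profile, compare,
                        match_distribution, risk_from_matched)

table = simulate_cohort(CohortConfig(n=5000, seed=1))
res = DistributionalRegression.from_survey(table).fit()
spec = res.model.design.spec

low  = reference_profile(spec, table, {"income": 20.0, "smoking": "no"})
high = reference_profile(spec, table, {"income": 80.0, "smoking": "no"})
print(res.risk_profile(low).as_series().round(3).to_dict())
print(res.risk_profile(high).as_series().round(3).to_dict())
print(compare(res.risk_profile(low), res.risk_profile(high)).round(3))
```

prints

```
{'E(h)': 0.806, 'sigma': 0.105, 'P_avg': 0.408, 'P_fair': 0.149, 'P_poor': 0.046}
{'E(h)': 0.813, 'sigma': 0.1,   'P_avg': 0.381, 'P_fair': 0.129, 'P_poor': 0.036}
             a      b  absolute_diff  relative_diff_pct
measure
E(h)     0.806  0.813         -0.007             -0.877
sigma    0.105  0.100          0.005              4.696
P_avg    0.408  0.381          0.026              6.471
P_fair   0.149  0.129          0.020             13.124
P_poor   0.046  0.036          0.009             20.098
```

The reference person (covariates at sample means / reference
categories) with a $20k income runs a 4.6% risk of poor health; at $80k
that risk drops to 3.6%.  The relative income effect grows toward the
lower tail (6% for average health, 20% for poor health) — the
distributional signature that mean regression cannot show.  The same
profile through the quantile-regression bridge:

```python
nine = QuantileRegression(res.model.design).fit_grid(np.arange(1, 10) / 10)
cdf = nine.empirical_cdf(low)                       # nine predicted quantiles
params = match_distribution(cdf.values, cdf.probs)  # gamma via CDF matching
print(risk_from_matched(params).as_series().round(3).to_dict())
# {'E(h)': 0.807, 'sigma': 0.107, 'P_avg': 0.401, 'P_fair': 0.15, 'P_poor': 0.048}
```

closely matching the direct distributional-regression estimates.

A `healthdist` command-line tool wraps the same pipeline
(`simulate`, `fit`, `quantiles`, `risk`, `report`); `healthdist report
--out results/` writes every stage as CSV.

## Limitations

Estimates are associational: no instruments or other endogeneity
corrections are attempted, survey weights and household clustering are
ignored, and the synthetic cohort draws covariates independently, so
real-data correlation structure is not emulated (see
`docs/methods.md`).
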