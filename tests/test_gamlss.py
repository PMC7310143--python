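"""Distributional regression: estimation, prediction, diagnostics, OLS."""

import numpy as np
import pytest
from scipy import stats

from healthdist import (
    CohortConfig,
    DistributionalRegression,
    encode,
    ols_fit,
    reference_profile,
    simulate_cohort,
    true_conditional_params,
)
from healthdist.design import DesignMatrix, DesignSpec
from healthdist.gamlss import information_criteria
from healthdist.risk import H0


@pytest.fixture(scope="module")
def fitted(cohort_design):
    return DistributionalRegression(cohort_design, family="gamma").fit()


def _intercept_design(h, ncols_extra=0):
    n = len(h)
    return DesignMatrix(
        endog=np.asarray(h, dtype=float),
        exog=np.ones((n, 1)),
        columns=["const"],
        column_kind={"const": "intercept"},
        spec=DesignSpec(age_center=44.87),
    )


def test_intercept_only_gamma_mle_is_sample_mean():
    rng = np.random.default_rng(0)
    h_star = rng.gamma(shape=4.0, scale=0.06, size=800)
    res = DistributionalRegression(_intercept_design(H0 - h_star)).fit()
    assert np.exp(res.params_mu[0]) == pytest.approx(h_star.mean(), abs=1e-6)


def test_full_model_deviance_not_worse_than_null(cohort_design, fitted):
    null = DistributionalRegression(_intercept_design(cohort_design.endog)).fit()
    assert fitted.deviance <= null.deviance


def test_deviance_trace_monotone(fitted):
    diffs = np.diff(fitted.deviance_trace)
    assert np.all(diffs <= 1e-9)


def test_information_criteria_arithmetic(fitted):
    p, n = fitted.df_model, fitted.nobs
    assert p == 54
    assert fitted.aic == pytest.approx(fitted.deviance + 2 * p)
    assert fitted.bic == pytest.approx(fitted.deviance + p * np.log(n))
    degenerate = information_criteria(-100.0, 0, 50)
    assert degenerate["aic"] == degenerate["bic"] == -100.0


def test_standard_errors_finite_positive(fitted):
    assert np.all(np.isfinite(fitted.bse_mu)) and np.all(fitted.bse_mu > 0)
    assert np.all(np.isfinite(fitted.bse_s)) and np.all(fitted.bse_s > 0)


def test_predict_params_income_ratio(fitted, cohort):
    spec = fitted.model.design.spec
    low = reference_profile(spec, cohort, {"income": 20.0})
    high = reference_profile(spec, cohort, {"income": 80.0})
    ratio = fitted.predict_params(high).mu / fitted.predict_params(low).mu
    beta_income = fitted.params_mu[fitted.model.columns.index("log_income")]
    assert ratio == pytest.approx(np.exp(beta_income * np.log(4)), rel=1e-10)


def test_predict_matches_generator_at_large_n():
    cfg = CohortConfig(n=30_000, seed=21)
    table = simulate_cohort(cfg)
    res = DistributionalRegression(encode(table, cfg.design_spec)).fit()
    profile = reference_profile(cfg.design_spec, table, {"income": 20.0, "smoking": "yes"})
    fit_p = res.predict_params(profile)
    true_p = true_conditional_params(profile, cfg)
    assert fit_p.mu == pytest.approx(true_p.mu, rel=0.01)
    assert fit_p.s == pytest.approx(true_p.s, rel=0.05)  # scale is noisier


def test_loglike_at_fit_not_systematically_below_truth():
    """The MLE should beat the generating parameters in-sample most of the
    time (and always up to optimization tolerance)."""
    wins = 0
    for seed in range(6):
        cfg = CohortConfig(n=1500, seed=100 + seed)
        table = simulate_cohort(cfg)
        dm = encode(table, cfg.design_spec)
        model = DistributionalRegression(dm)
        res = model.fit()
        beta_mu, beta_s = cfg.coefficient_vectors(dm.columns)
        if res.llf >= model.loglike(beta_mu, beta_s) - 1e-6:
            wins += 1
    assert wins >= 3


def test_quantile_residuals_standard_normal_under_truth():
    cfg = CohortConfig(n=5_000, seed=23)
    table = simulate_cohort(cfg)
    res = DistributionalRegression(encode(table, cfg.design_spec)).fit()
    resid, skew, kurt = res.quantile_residuals()
    assert stats.kstest(resid, "norm").pvalue > 0.01
    assert abs(skew) < 0.2
    assert abs(kurt - 3.0) < 0.5


def test_misspecified_family_shows_skewed_residuals():
    """Lognormal data fitted with a gamma at small shape leaves clearly
    more residual skewness than the true family does."""
    rng = np.random.default_rng(3)
    draws = rng.lognormal(mean=-2.0, sigma=0.9, size=8000)
    h_star = draws[draws < H0 - 1e-6][:4000]  # ~1% rejected to keep h in range
    design = _intercept_design(H0 - h_star)
    gamma_fit = DistributionalRegression(design, family="gamma").fit()
    logno_fit = DistributionalRegression(design, family="lognormal").fit()
    _, skew_gamma, _ = gamma_fit.quantile_residuals()
    _, skew_logno, _ = logno_fit.quantile_residuals()
    assert abs(skew_gamma) > abs(skew_logno)


def test_rank_deficiency_detected(cohort_design):
    exog = np.column_stack([cohort_design.exog, cohort_design.exog[:, 0]])
    dm = DesignMatrix(
        endog=cohort_design.endog,
        exog=exog,
        columns=cohort_design.columns + ["dup"],
        column_kind={**cohort_design.column_kind, "dup": "numeric"},
        spec=cohort_design.spec,
    )
    with pytest.raises(ValueError, match="rank deficient"):
        DistributionalRegression(dm)


def test_summary_mentions_fit_quality(fitted):
    text = fitted.summary()
    assert "Global deviance" in text and "log_income" in text


def test_ols_intercept_only_is_mean():
    rng = np.random.default_rng(1)
    h = rng.uniform(size=200)
    beta = ols_fit(_intercept_design(h))
    assert beta[0] == pytest.approx(h.mean(), rel=1e-12)


def test_ols_matches_normal_equations_and_orthogonality():
    rng = np.random.default_rng(2)
    X = np.column_stack([np.ones(10), rng.normal(size=(10, 2))])
    y = rng.normal(size=10)
    dm = DesignMatrix(
        endog=y,
        exog=X,
        columns=["const", "x1", "x2"],
        column_kind={"const": "intercept", "x1": "numeric", "x2": "numeric"},
        spec=DesignSpec(age_center=44.87),
    )
    beta = ols_fit(dm)
    brute = np.linalg.solve(X.T @ X, X.T @ y)
    assert beta == pytest.approx(brute, abs=1e-10)
    resid = y - X @ beta
    assert np.max(np.abs(X.T @ resid)) < 1e-8
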