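"""Quantile regression: LP correctness, grids, CDF inversion."""

from itertools import combinations

import numpy as np
import pytest

from healthdist import DistParams, QuantileRegression, reference_profile
from healthdist import families
from healthdist.design import DesignMatrix, DesignSpec
from healthdist.quantile import EmpiricalCDF, check_loss
from healthdist.risk import H0


def _design(y, X, names=None):
    names = names or [f"x{i}" for i in range(X.shape[1])]
    return DesignMatrix(
        endog=np.asarray(y, dtype=float),
        exog=np.asarray(X, dtype=float),
        columns=names,
        column_kind={n: "numeric" for n in names},
        spec=DesignSpec(age_center=44.87),
    )


@pytest.mark.parametrize("tau", [0.1, 0.25, 0.5, 0.7, 0.9])
def test_intercept_only_equals_sample_quantile(intercept_design, tau):
    rng = np.random.default_rng(12)
    h = rng.uniform(size=41)
    fit = QuantileRegression(intercept_design(h)).fit(tau)
    oracle = np.quantile(h, tau, method="inverted_cdf")
    # the minimizer may be any point of the optimal interval; the attained
    # loss is the invariant quantity
    assert fit.loss == pytest.approx(check_loss(h - oracle, tau), abs=1e-9)


def test_intercept_only_monotone_in_tau(intercept_design):
    rng = np.random.default_rng(13)
    h = rng.normal(size=60)
    model = QuantileRegression(intercept_design(h))
    consts = [model.fit(t).params[0] for t in (0.1, 0.5, 0.9)]
    assert consts == sorted(consts)
    assert consts[0] <= np.median(h) <= consts[2]


def test_lp_matches_exhaustive_basic_solution_search():
    """With p=2 some optimal fit interpolates two observations; the LP
    objective must match the best interpolating fit's check loss."""
    rng = np.random.default_rng(7)
    X = np.column_stack([np.ones(6), rng.normal(size=6)])
    y = rng.normal(size=6)
    model = QuantileRegression(_design(y, X))
    for tau in (0.3, 0.5, 0.8):
        best = np.inf
        for i, j in combinations(range(6), 2):
            sub = X[[i, j]]
            if abs(np.linalg.det(sub)) < 1e-12:
                continue
            beta = np.linalg.solve(sub, y[[i, j]])
            best = min(best, check_loss(y - X @ beta, tau))
        assert model.fit(tau).loss == pytest.approx(best, abs=1e-9)


def test_agrees_with_statsmodels_quantreg(cohort_design):
    """Independent cross-check: the IRLS implementation in statsmodels
    should reach (essentially) the same minimum check loss."""
    import statsmodels.api as sm

    sub = DesignMatrix(
        endog=cohort_design.endog[:400],
        exog=cohort_design.exog[:400],
        columns=cohort_design.columns,
        column_kind=cohort_design.column_kind,
        spec=cohort_design.spec,
    )
    ours = QuantileRegression(sub).fit(0.5)
    theirs = sm.QuantReg(sub.endog, sub.exog).fit(q=0.5)
    loss_theirs = check_loss(sub.endog - sub.exog @ np.asarray(theirs.params), 0.5)
    assert ours.loss <= loss_theirs + 1e-6
    assert ours.loss == pytest.approx(loss_theirs, rel=1e-3)


def test_check_loss_scales_with_row_duplication():
    rng = np.random.default_rng(8)
    X = np.column_stack([np.ones(30), rng.normal(size=30)])
    y = X @ np.array([0.5, 0.2]) + rng.normal(scale=0.1, size=30)
    single = QuantileRegression(_design(y, X)).fit(0.3)
    doubled = QuantileRegression(_design(np.tile(y, 2), np.tile(X, (2, 1)))).fit(0.3)
    assert doubled.loss == pytest.approx(2 * single.loss, rel=1e-8)


def test_pseudo_r2_bounds(intercept_design):
    rng = np.random.default_rng(9)
    h = rng.uniform(size=80)
    null_fit = QuantileRegression(intercept_design(h)).fit(0.5)
    assert null_fit.pseudo_r2 == pytest.approx(0.0, abs=1e-9)

    X = np.column_stack([np.ones(80), rng.normal(size=80)])
    exact = X @ np.array([1.0, 0.4])
    perfect = QuantileRegression(_design(exact, X)).fit(0.5)
    assert perfect.pseudo_r2 == pytest.approx(1.0, abs=1e-9)

    noisy = QuantileRegression(_design(exact + rng.normal(scale=0.3, size=80), X)).fit(0.5)
    assert 0.0 < noisy.pseudo_r2 < 1.0


def test_invalid_tau_and_grid():
    rng = np.random.default_rng(10)
    model = QuantileRegression(_design(rng.uniform(size=10), np.ones((10, 1))))
    with pytest.raises(ValueError):
        model.fit(1.2)
    with pytest.raises(ValueError):
        model.fit_grid([0.5, 0.4])


def test_grid_of_one_equals_single_fit(intercept_design):
    rng = np.random.default_rng(11)
    h = rng.uniform(size=50)
    model = QuantileRegression(intercept_design(h))
    grid = model.fit_grid([0.5])
    assert len(grid) == 1
    assert grid[0].params == pytest.approx(model.fit(0.5).params)


def test_profile_prediction_income_contrast(cohort, cohort_design):
    model = QuantileRegression(cohort_design)
    fit = model.fit(0.5)
    spec = cohort_design.spec
    low = reference_profile(spec, cohort, {"income": 20.0})
    high = reference_profile(spec, cohort, {"income": 80.0})
    beta_income = fit.params[cohort_design.columns.index("log_income")]
    assert fit.predict(high) - fit.predict(low) == pytest.approx(
        beta_income * np.log(4), rel=1e-10
    )


def test_location_shift_model_brackets_true_median():
    rng = np.random.default_rng(14)
    n = 2000
    x = rng.normal(size=n)
    y = 1.0 + 0.5 * x + rng.normal(scale=0.3, size=n)
    X = np.column_stack([np.ones(n), x])
    model = QuantileRegression(_design(y, X))
    row = np.array([1.0, 0.7])
    true_median = 1.0 + 0.5 * 0.7
    lo = model.fit(0.4).predict(row)
    hi = model.fit(0.6).predict(row)
    assert lo <= true_median <= hi


def test_empirical_cdf_rearrangement():
    values = np.array([0.6, 0.72, 0.7, 0.8])  # one crossed pair
    taus = np.array([0.2, 0.4, 0.6, 0.8])

    class _Fake:
        def __init__(self, v):
            self.v = v

        def predict(self, profile):
            return self.v

    from healthdist.quantile import QuantileFitSet

    fs = QuantileFitSet(taus=taus, fits=[_Fake(v) for v in values])
    cdf = fs.empirical_cdf(profile=None)
    assert cdf.crossings == 1
    assert cdf.values == pytest.approx([0.6, 0.7, 0.72, 0.8])
    assert cdf.probs == pytest.approx(taus)

    monotone = QuantileFitSet(taus=taus, fits=[_Fake(v) for v in sorted(values)])
    assert monotone.empirical_cdf(None).crossings == 0


def test_empirical_cdf_from_analytic_quantiles_inverts_exactly():
    p = DistParams("gamma", 0.2131, 0.4411)  # on the h* scale
    taus = np.arange(1, 1000) / 1000.0
    h_quantiles = H0 - families.quantile(1.0 - taus, p)  # h^tau, increasing
    cdf = EmpiricalCDF(values=np.sort(h_quantiles), probs=taus)
    # grid values are exact quantiles, so inversion is exact at the grid
    for tau in (0.1, 0.5, 0.9):
        k = int(round(tau * 1000)) - 1
        assert cdf.tail_prob(cdf.values[k]) == pytest.approx(taus[k], abs=1e-10)
    # threshold h = 0.6: step inversion close to the analytic survival
    analytic = float(families.sf(H0 - 0.6, p))
    assert cdf.tail_prob(0.6) == pytest.approx(analytic, abs=0.002)
    # boundary behaviour
    assert cdf.tail_prob(cdf.values.min() - 0.01) == 0.0
    assert cdf.tail_prob(1.0) == pytest.approx(0.999)


def test_tail_prob_monotone_in_threshold():
    rng = np.random.default_rng(15)
    values = np.sort(rng.uniform(0.4, 0.95, size=9))
    cdf = EmpiricalCDF(values=values, probs=np.arange(1, 10) / 10.0)
    probs = [cdf.tail_prob(t) for t in np.linspace(0.3, 1.0, 29)]
    assert all(a <= b for a, b in zip(probs, probs[1:]))


def test_bootstrap_se_deterministic(intercept_design):
    rng = np.random.default_rng(16)
    h = rng.uniform(size=40)
    model = QuantileRegression(intercept_design(h))
    grid = model.fit_grid([0.25, 0.75])
    a = grid.bootstrap_se(n_boot=20, seed=1)
    b = grid.bootstrap_se(n_boot=20, seed=1)
    assert a.equals(b)
    assert (a.to_numpy() > 0).all()
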