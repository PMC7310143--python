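"""Linear conditional quantile regression by check-loss minimization.

For a quantile level tau in (0, 1) the fit minimizes

    sum_i rho_tau(h_i - x_i' beta),   rho_tau(u) = u * (tau - 1{u < 0}),

which is solved exactly as a linear program (HiGHS, via
scipy.optimize.linprog) in the standard primal formulation with split
positive/negative residuals.  A grid of fits across tau levels yields,
for any covariate profile, a set of predicted conditional quantiles;
sorting those (monotone rearrangement, which resolves quantile crossing)
and pairing them with their tau levels gives a step-function estimate of
the conditional CDF of health, whose inversion provides non-parametric
tail-risk probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, sparse

from .design import DesignMatrix, encode_profile

logger = logging.getLogger(__name__)

__all__ = [
    "check_loss",
    "QuantileRegression",
    "QuantileRegResults",
    "QuantileFitSet",
    "EmpiricalCDF",
    "nine_point_grid",
    "thousand_point_grid",
]


def nine_point_grid() -> np.ndarray:
    return np.arange(1, 10) / 10.0


def thousand_point_grid() -> np.ndarray:
    return np.arange(1, 1000) / 1000.0


def check_loss(residuals, tau: float) -> float:
    u = np.asarray(residuals, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


class QuantileRegression:
    """Conditional quantile regression model over an encoded design."""

    def __init__(self, design: DesignMatrix):
        if np.any(~np.isfinite(design.endog)):
            raise ValueError("response contains non-finite values")
        self.design = design
        self.exog = design.exog
        self.endog = np.asarray(design.endog, dtype=float)

    def fit(self, tau: float) -> "QuantileRegResults":
        """Exact LP solution of the check-loss problem at one tau.

        Degenerate problems can have multiple minimizers; any global
        minimizer is acceptable and the attained loss is what tests
        should assert on.
        """
        if not 0.0 < tau < 1.0:
            raise ValueError(f"tau must be in (0, 1), got {tau}")
        n, p = self.exog.shape
        # variables: beta (free), u >= 0, v >= 0 with X beta + u - v = h
        cost = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
        eye = sparse.eye(n, format="csc")
        a_eq = sparse.hstack([sparse.csc_matrix(self.exog), eye, -eye], format="csc")
        bounds = [(None, None)] * p + [(0, None)] * (2 * n)
        res = optimize.linprog(
            cost, A_eq=a_eq, b_eq=self.endog, bounds=bounds, method="highs"
        )
        if not res.success:
            raise RuntimeError(f"LP solver failed at tau={tau}: {res.message}")
        beta = res.x[:p]
        loss = check_loss(self.endog - self.exog @ beta, tau)
        return QuantileRegResults(self, float(tau), beta, loss)

    def null_loss(self, tau: float) -> float:
        """Check loss of the best constant fit (the tau-th sample quantile)."""
        q = np.quantile(self.endog, tau, method="inverted_cdf")
        return check_loss(self.endog - q, tau)

    def fit_grid(self, taus) -> "QuantileFitSet":
        """Independent fits over a strictly increasing tau grid."""
        taus = np.asarray(taus, dtype=float)
        if taus.ndim != 1 or len(taus) == 0:
            raise ValueError("tau grid must be a non-empty 1-d sequence")
        if np.any(np.diff(taus) <= 0) or np.any((taus <= 0) | (taus >= 1)):
            raise ValueError("tau grid must be strictly increasing within (0, 1)")
        fits = []
        for i, tau in enumerate(taus):
            try:
                fits.append(self.fit(float(tau)))
            except Exception as exc:
                raise RuntimeError(f"quantile fit failed at tau={tau}") from exc
            if (i + 1) % 100 == 0:
                logger.info("fitted %d/%d quantile regressions", i + 1, len(taus))
        return QuantileFitSet(taus=taus, fits=fits)


class QuantileRegResults:
    """One fitted quantile regression: coefficients, loss, pseudo-R^2."""

    def __init__(self, model: QuantileRegression, tau: float, params, loss: float):
        self.model = model
        self.tau = tau
        self.params = np.asarray(params, dtype=float)
        self.loss = loss
        self._null_loss: float | None = None

    @property
    def pseudo_r2(self) -> float:
        """1 - loss / loss(intercept-only); 0 for the null model, 1 for
        a perfect fit (Koenker-Machado style goodness of fit)."""
        if self._null_loss is None:
            self._null_loss = self.model.null_loss(self.tau)
        if self._null_loss == 0.0:
            raise ZeroDivisionError("null model has zero check loss; pseudo-R2 undefined")
        return 1.0 - self.loss / self._null_loss

    def predict(self, profile) -> float:
        """Predicted conditional tau-quantile of health for a profile."""
        if isinstance(profile, dict):
            row = encode_profile(profile, self.model.design.spec)
        else:
            row = np.asarray(profile, dtype=float)
        return float(row @ self.params)


@dataclass
class EmpiricalCDF:
    """Step-function CDF built from predicted quantiles.

    ``values`` are non-decreasing (after rearrangement) and ``probs``
    strictly increasing; ``crossings`` counts how many adjacent predicted
    quantiles had to be reordered.
    """

    values: np.ndarray
    probs: np.ndarray
    crossings: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(np.diff(self.probs) <= 0):
            raise ValueError("probabilities must be strictly increasing")
        if np.any(np.diff(self.values) < 0):
            raise ValueError("values must be non-decreasing; rearrange first")

    def tail_prob(self, threshold: float) -> float:
        """P(h <= threshold): the largest tau whose quantile is <= the
        threshold, 0 below the smallest predicted quantile."""
        below = self.probs[self.values <= threshold]
        return float(below.max()) if below.size else 0.0


class QuantileFitSet:
    """Ordered collection of quantile fits over a tau grid."""

    def __init__(self, taus: np.ndarray, fits: list[QuantileRegResults]):
        self.taus = np.asarray(taus, dtype=float)
        self.fits = list(fits)

    def __len__(self) -> int:
        return len(self.fits)

    def __getitem__(self, i: int) -> QuantileRegResults:
        return self.fits[i]

    def predict_quantiles(self, profile) -> np.ndarray:
        """Predicted conditional quantiles at every tau, unsorted."""
        return np.array([fit.predict(profile) for fit in self.fits])

    def empirical_cdf(self, profile) -> EmpiricalCDF:
        """Monotone conditional CDF estimate for one profile.

        Predicted quantiles are sorted before pairing with the tau grid;
        sorting preserves the marginal set of predictions and restores
        the monotonicity that CDF inversion requires.
        """
        if len(self.fits) < 2:
            raise ValueError("need at least two quantile fits for a CDF")
        raw = self.predict_quantiles(profile)
        crossings = int(np.sum(np.diff(raw) < 0))
        if crossings:
            logger.info("monotone rearrangement fixed %d crossings", crossings)
        return EmpiricalCDF(values=np.sort(raw), probs=self.taus, crossings=crossings)

    def coef_frame(self) -> pd.DataFrame:
        """Tau-by-coefficient table (one row per tau)."""
        frame = pd.DataFrame(
            [fit.params for fit in self.fits],
            columns=self.fits[0].model.design.columns,
        )
        frame.insert(0, "tau", self.taus)
        return frame

    def bootstrap_se(self, n_boot: int = 200, seed: int = 0) -> pd.DataFrame:
        """Pairs-bootstrap standard errors for every tau and coefficient.

        Rows (h_i, x_i) are resampled with replacement and each tau
        refitted; the SE is the SD of the replicate coefficients.
        """
        design = self.fits[0].model.design
        n = design.nobs
        rng = np.random.default_rng(seed)
        reps = {float(t): [] for t in self.taus}
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            sub = DesignMatrix(
                endog=design.endog[idx],
                exog=design.exog[idx],
                columns=design.columns,
                column_kind=design.column_kind,
                spec=design.spec,
            )
            model = QuantileRegression(sub)
            for t in self.taus:
                reps[float(t)].append(model.fit(float(t)).params)
        rows = {t: np.std(np.array(v), axis=0, ddof=1) for t, v in reps.items()}
        frame = pd.DataFrame.from_dict(rows, orient="index", columns=design.columns)
        frame.index.name = "tau"
        return frame
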