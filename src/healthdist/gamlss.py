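"""Maximum-likelihood distributional regression (location-scale-shape).

Both parameters of a two-parameter family get their own linear predictor
over the same design:

    link(mu_i) = x_i' beta_mu        log(s_i) = x_i' beta_s

with a log link on mu for the gamma and mean-parameterized Weibull
families and an identity link for the lognormal location (which lives on
the log scale and is typically negative here).  Estimation alternates
Newton/Fisher-scoring updates of the two coefficient blocks with
step-halving, so the global deviance decreases monotonically, until the
deviance change falls below tolerance.  Standard errors come from the
observed information of the joint coefficient vector.

The model is fitted to the reflected health score h* = 1.0001 - h, which
is positive and positively skewed; all predictions are on that scale and
are converted back to health by the risk module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from . import families
from .design import DesignMatrix, DesignSpec, encode, encode_profile
from .risk import H0, RiskProfile, risk_measures

__all__ = [
    "DistributionalRegression",
    "DistRegResults",
    "ols_fit",
    "information_criteria",
]


def information_criteria(deviance: float, n_params: int, nobs: int) -> dict[str, float]:
    """AIC = deviance + 2p and BIC = deviance + p log(n).

    ``n_params`` counts coefficients across both predictors (2 x 27 for
    the standard design); with p = 0 both criteria equal the deviance.
    """
    return {
        "deviance": deviance,
        "aic": deviance + 2.0 * n_params,
        "bic": deviance + n_params * (np.log(nobs) if n_params else 0.0),
    }

_FD_STEP = 1e-5  # central-difference step on the predictor scale


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def _check_full_rank(exog: np.ndarray, columns: list[str]) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name a minimal set of columns involved in the collinearity
        _, r = np.linalg.qr(exog)
        small = np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max()
        offenders = [c for c, flag in zip(columns, small) if flag]
        raise ValueError(f"design is rank deficient (rank {rank} < {exog.shape[1]}); "
                         f"suspect columns {offenders}")


def _loglike_terms(family: str, y: np.ndarray, eta_mu, eta_s) -> np.ndarray:
    """Per-observation log-likelihood as a function of the two predictors."""
    s = np.exp(eta_s)
    mu = eta_mu if family == "lognormal" else np.exp(eta_mu)
    return families._frozen(family, mu, s).logpdf(y)


def _block_derivs(family, y, eta_mu, eta_s, block: str):
    """Per-observation score and positive curvature for one predictor block.

    Gamma and lognormal use closed forms (expected information); the
    mean-parameterized Weibull falls back to central finite differences
    of the log-likelihood in the predictor.
    """
    s = np.exp(eta_s)
    if family == "gamma":
        mu = np.exp(eta_mu)
        if block == "mu":
            return (y - mu) / (s**2 * mu), 1.0 / s**2
        d = 1.0 / s**2
        score = -2.0 * d * (np.log(y) - y / mu - np.log(s**2 * mu) - special.digamma(d) + 1.0)
        weight = 4.0 * d**2 * special.polygamma(1, d) - 4.0 * d
        return score, np.maximum(weight, 1e-10)
    if family == "lognormal":
        z = (np.log(y) - eta_mu) / s
        if block == "mu":
            return z / s, 1.0 / s**2
        return z**2 - 1.0, np.full_like(y, 2.0)
    # weibull3: numeric
    h = _FD_STEP
    if block == "mu":
        lp = lambda e: _loglike_terms(family, y, e, eta_s)  # noqa: E731
        base = eta_mu
    else:
        lp = lambda e: _loglike_terms(family, y, eta_mu, e)  # noqa: E731
        base = eta_s
    up, mid, down = lp(base + h), lp(base), lp(base - h)
    score = (up - down) / (2 * h)
    curv = -(up - 2 * mid + down) / h**2
    return score, np.maximum(curv, 1e-10)


@dataclass
class _FitOptions:
    tol: float = 1e-6
    maxiter: int = 200
    inner_newton: int = 5
    max_halvings: int = 30


class DistributionalRegression:
    """Distributional regression model for a bounded health score.

    Parameters
    ----------
    design : DesignMatrix
        Encoded covariates with the health score as response; the
        response is reflected internally to h* = 1.0001 - h > 0.
    family : str
        'gamma' (default), 'weibull3' or 'lognormal'.
    """

    def __init__(self, design: DesignMatrix, family: str = "gamma"):
        if family not in families.FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        _check_full_rank(design.exog, design.columns)
        y_star = H0 - np.asarray(design.endog, dtype=float)
        if np.any(~np.isfinite(y_star)) or np.any(y_star <= 0):
            raise ValueError("response must be finite with h < 1.0001")
        self.design = design
        self.family = family
        self.endog_star = y_star
        self.exog = design.exog
        self.columns = design.columns

    @classmethod
    def from_survey(
        cls, table: pd.DataFrame, family: str = "gamma", spec: DesignSpec | None = None
    ) -> "DistributionalRegression":
        return cls(encode(table, spec), family)

    # -- likelihood ---------------------------------------------------

    def loglike(self, beta_mu: np.ndarray, beta_s: np.ndarray) -> float:
        terms = _loglike_terms(
            self.family, self.endog_star, self.exog @ beta_mu, self.exog @ beta_s
        )
        return float(np.sum(terms))

    def _start_values(self) -> tuple[np.ndarray, np.ndarray]:
        y = self.endog_star
        p0 = families.params_from_moments(self.family, float(y.mean()), float(y.std(ddof=1)))
        beta_mu = np.zeros(len(self.columns))
        beta_s = np.zeros(len(self.columns))
        intercept = self.columns.index("const")
        beta_mu[intercept] = p0.mu if self.family == "lognormal" else np.log(p0.mu)
        beta_s[intercept] = np.log(p0.s)
        return beta_mu, beta_s

    def _update_block(self, beta_mu, beta_s, block, opts) -> tuple[np.ndarray, float]:
        """Newton steps with step-halving for one coefficient block."""
        X = self.exog
        beta = beta_mu if block == "mu" else beta_s
        current = self.loglike(beta_mu, beta_s)
        for _ in range(opts.inner_newton):
            eta_mu, eta_s = X @ beta_mu, X @ beta_s
            score, weight = _block_derivs(self.family, self.endog_star, eta_mu, eta_s, block)
            grad = X.T @ score
            hess = X.T @ (weight[:, None] * X)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.solve(hess + 1e-8 * np.eye(len(grad)), grad)
            scale = 1.0
            improved = False
            for _ in range(opts.max_halvings):
                trial = beta + scale * step
                if block == "mu":
                    candidate = self.loglike(trial, beta_s)
                else:
                    candidate = self.loglike(beta_mu, trial)
                if np.isfinite(candidate) and candidate >= current - 1e-12:
                    beta = trial
                    if block == "mu":
                        beta_mu = trial
                    else:
                        beta_s = trial
                    improved = candidate > current
                    current = candidate
                    break
                scale /= 2.0
            if not improved:
                break
        return beta, current

    def fit(self, tol: float = 1e-6, maxiter: int = 200) -> "DistRegResults":
        """Alternate scoring updates of beta_mu and beta_s to convergence.

        Convergence is declared when the global deviance (-2 loglik)
        changes by less than ``tol`` between outer iterations; failure to
        converge raises with the deviance trace attached.
        """
        opts = _FitOptions(tol=tol, maxiter=maxiter)
        beta_mu, beta_s = self._start_values()
        deviance = -2.0 * self.loglike(beta_mu, beta_s)
        trace = [deviance]
        for iteration in range(1, maxiter + 1):
            beta_mu, _ = self._update_block(beta_mu, beta_s, "mu", opts)
            beta_s, llf = self._update_block(beta_mu, beta_s, "s", opts)
            new_deviance = -2.0 * llf
            trace.append(new_deviance)
            if abs(deviance - new_deviance) < tol:
                return DistRegResults(self, beta_mu, beta_s, llf, iteration, trace)
            deviance = new_deviance
        raise ConvergenceError(
            f"no convergence in {maxiter} outer iterations "
            f"(last deviance change {abs(trace[-2] - trace[-1]):.3g})",
            trace,
        )

    # -- inference helpers --------------------------------------------

    def observed_information(self, beta_mu, beta_s) -> np.ndarray:
        """Joint observed information via per-observation numeric curvature."""
        X = self.exog
        y = self.endog_star
        e_mu, e_s = X @ beta_mu, X @ beta_s
        h = _FD_STEP
        lp = lambda a, b: _loglike_terms(self.family, y, a, b)  # noqa: E731
        mid = lp(e_mu, e_s)
        d2_mm = (lp(e_mu + h, e_s) - 2 * mid + lp(e_mu - h, e_s)) / h**2
        d2_ss = (lp(e_mu, e_s + h) - 2 * mid + lp(e_mu, e_s - h)) / h**2
        d2_ms = (
            lp(e_mu + h, e_s + h)
            - lp(e_mu + h, e_s - h)
            - lp(e_mu - h, e_s + h)
            + lp(e_mu - h, e_s - h)
        ) / (4 * h**2)
        block = lambda d2: X.T @ (-d2[:, None] * X)  # noqa: E731
        top = np.hstack([block(d2_mm), block(d2_ms)])
        bottom = np.hstack([block(d2_ms), block(d2_ss)])
        return np.vstack([top, bottom])


class DistRegResults:
    """Fitted distributional regression with inference and diagnostics."""

    def __init__(self, model, beta_mu, beta_s, llf, iterations, trace):
        self.model = model
        self.params_mu = np.asarray(beta_mu, dtype=float)
        self.params_s = np.asarray(beta_s, dtype=float)
        self.llf = float(llf)
        self.iterations = iterations
        self.deviance_trace = list(trace)
        self._cov: np.ndarray | None = None

    # -- goodness of fit ----------------------------------------------

    @property
    def deviance(self) -> float:
        """Global deviance, -2 times the maximized log-likelihood."""
        return -2.0 * self.llf

    @property
    def df_model(self) -> int:
        return len(self.params_mu) + len(self.params_s)

    @property
    def nobs(self) -> int:
        return self.model.exog.shape[0]

    @property
    def aic(self) -> float:
        return information_criteria(self.deviance, self.df_model, self.nobs)["aic"]

    @property
    def bic(self) -> float:
        return information_criteria(self.deviance, self.df_model, self.nobs)["bic"]

    def information_criteria(self) -> dict[str, float]:
        return information_criteria(self.deviance, self.df_model, self.nobs)

    # -- uncertainty ---------------------------------------------------

    @property
    def cov_params(self) -> np.ndarray:
        if self._cov is None:
            info = self.model.observed_information(self.params_mu, self.params_s)
            self._cov = np.linalg.inv(info)
        return self._cov

    @property
    def bse_mu(self) -> np.ndarray:
        p = len(self.params_mu)
        return np.sqrt(np.diag(self.cov_params)[:p])

    @property
    def bse_s(self) -> np.ndarray:
        p = len(self.params_mu)
        return np.sqrt(np.diag(self.cov_params)[p:])

    # -- prediction ----------------------------------------------------

    def _params_from_row(self, row: np.ndarray) -> families.DistParams:
        eta_mu = float(row @ self.params_mu)
        eta_s = float(row @ self.params_s)
        mu = eta_mu if self.model.family == "lognormal" else np.exp(eta_mu)
        return families.DistParams(self.model.family, mu, float(np.exp(eta_s)))

    def predict_params(self, profile) -> families.DistParams:
        """Conditional (mu, s) on the h* scale for a covariate profile.

        ``profile`` is either a covariate dict or an already-encoded
        design row.
        """
        if isinstance(profile, dict):
            row = encode_profile(profile, self.model.design.spec)
        else:
            row = np.asarray(profile, dtype=float)
            if row.shape != (len(self.model.columns),):
                raise ValueError(
                    f"design row must have {len(self.model.columns)} entries"
                )
        return self._params_from_row(row)

    def risk_profile(self, profile, thresholds=None) -> RiskProfile:
        """Tail-risk measures of health for one covariate profile."""
        return risk_measures(self.predict_params(profile), thresholds, source="gamlss")

    # -- diagnostics ---------------------------------------------------

    def quantile_residuals(self):
        """Normalized quantile residuals with their skewness and kurtosis.

        r_i = Phi^{-1}(F(h*_i | mu_i, s_i)); standard normal when the
        assumed family is correct.  The response is continuous, so no
        randomization is involved; CDF values of exactly 0 or 1 are
        clamped to [1e-12, 1 - 1e-12].
        """
        X = self.model.exog
        eta_mu, eta_s = X @ self.params_mu, X @ self.params_s
        s = np.exp(eta_s)
        mu = eta_mu if self.model.family == "lognormal" else np.exp(eta_mu)
        u = families._frozen(self.model.family, mu, s).cdf(self.model.endog_star)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        resid = stats.norm.ppf(u)
        return resid, float(stats.skew(resid)), float(stats.kurtosis(resid, fisher=False))

    # -- display -------------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        def stars(est, se):
            z = np.abs(est) / se
            p = 2 * stats.norm.sf(z)
            return np.where(p < 0.01, "**", np.where(p < 0.05, "*", ""))

        return pd.DataFrame(
            {
                "coef_mu": self.params_mu,
                "se_mu": self.bse_mu,
                "sig_mu": stars(self.params_mu, self.bse_mu),
                "coef_s": self.params_s,
                "se_s": self.bse_s,
                "sig_s": stars(self.params_s, self.bse_s),
            },
            index=self.model.columns,
        )

    def summary(self) -> str:
        frame = self.summary_frame()
        lines = [
            f"Distributional regression ({self.model.family}), "
            f"n={self.nobs}, {self.iterations} outer iterations",
            f"{'variable':<26}{'log(mu)':>12}{'':<3}{'log(s)':>12}",
        ]
        for name, row in frame.iterrows():
            lines.append(
                f"{name:<26}{row.coef_mu:>12.4f}{row.sig_mu:<3}"
                f"{row.coef_s:>12.4f}{row.sig_s:<3}"
            )
        lines.append(
            f"Global deviance {self.deviance:,.2f}   AIC {self.aic:,.2f}   "
            f"BIC {self.bic:,.2f}"
        )
        return "\n".join(lines)


def ols_fit(design: DesignMatrix) -> np.ndarray:
    """Ordinary least squares of health on the design (comparison baseline)."""
    _check_full_rank(design.exog, design.columns)
    import statsmodels.api as sm

    return np.asarray(sm.OLS(design.endog, design.exog).fit().params)
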