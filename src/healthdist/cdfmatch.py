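"""Estimating a parametric distribution from predicted quantiles.

Given K predicted health quantiles h^(tau_k) from quantile regression,
the reflected values h*_k = 1.0001 - h^(tau_k) satisfy
P(h* <= h*_k) = 1 - tau_k, so each (h*_k, 1 - tau_k) pair is a point on
the CDF of the transformed score.  The two parameters of a family are
estimated by least squares between these empirical CDF values and the
theoretical CDF:

    min_{mu, s}  sum_k (1 - tau_k - F(h*_k; mu, s))^2

with equal weights.  The optimization runs unconstrained in
(log mu, log s) (plain (mu, log s) for the lognormal location), started
from moment-matching of the K reflected quantiles, using Nelder-Mead
followed by a BFGS polish.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from . import families
from .families import DistParams
from .risk import H0, RiskProfile, risk_measures

__all__ = ["match_distribution", "match_objective", "risk_from_matched"]


def _pack(params: DistParams) -> np.ndarray:
    if params.family == "lognormal":
        return np.array([params.mu, np.log(params.s)])
    return np.array([np.log(params.mu), np.log(params.s)])


def _unpack(x: np.ndarray, family: str) -> DistParams:
    if family == "lognormal":
        return DistParams(family, float(x[0]), float(np.exp(x[1])))
    return DistParams(family, float(np.exp(x[0])), float(np.exp(x[1])))


def match_objective(params: DistParams, quantiles_h, taus) -> float:
    """Sum of squared CDF residuals for quantiles given on the h scale."""
    taus = np.asarray(taus, dtype=float)
    h_star = H0 - np.asarray(quantiles_h, dtype=float)
    resid = (1.0 - taus) - families.cdf(h_star, params)
    return float(np.sum(resid**2))


def match_distribution(quantiles_h, taus, family: str = "gamma") -> DistParams:
    """Least-squares CDF matching of a two-parameter family.

    Parameters
    ----------
    quantiles_h : array
        Predicted health quantiles on the original [0, 1] scale,
        increasing with tau; reflected internally, so callers never
        handle the 1 - tau reversal.
    taus : array
        Strictly increasing quantile levels in (0, 1), length >= 2.
    """
    quantiles_h = np.asarray(quantiles_h, dtype=float)
    taus = np.asarray(taus, dtype=float)
    if len(quantiles_h) != len(taus) or len(taus) < 2:
        raise ValueError("need K >= 2 quantiles with matching tau levels")
    if np.any(np.diff(taus) <= 0) or np.any((taus <= 0) | (taus >= 1)):
        raise ValueError("tau levels must be strictly increasing within (0, 1)")
    h_star = H0 - quantiles_h
    if np.any((h_star <= 0) | (h_star >= H0)):
        raise ValueError("quantiles must lie strictly inside (0.0001, 1.0001) after reflection")

    start = families.params_from_moments(
        family, float(h_star.mean()), float(h_star.std(ddof=1))
    )
    objective = lambda x: match_objective(_unpack(x, family), quantiles_h, taus)  # noqa: E731
    x0 = _pack(start)
    simplex = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
    )
    polish = optimize.minimize(objective, simplex.x, method="BFGS")
    best = polish if polish.fun <= simplex.fun else simplex
    if not np.all(np.isfinite(best.x)):
        raise RuntimeError(f"CDF matching failed to converge: {best.message}")
    if best.fun > objective(x0) + 1e-12:
        raise RuntimeError("CDF matching ended above its moment-matching start")
    return _unpack(best.x, family)


def risk_from_matched(params: DistParams, thresholds=None) -> RiskProfile:
    """Risk profile from CDF-matched parameters (parametric route)."""
    return risk_measures(params, thresholds, source="parametric-from-quantiles")
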