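"""Two-parameter distribution families for the transformed health score.

All three families are parameterized by a location parameter ``mu`` and a
scale parameter ``s``, both strictly positive, matching the conventions of
the GAMLSS literature:

``gamma`` (GA)
    Shape ``1/s**2`` and scale ``s**2 * mu``, so that ``E(X) = mu`` and
    ``SD(X) = s * mu`` (``s`` is the coefficient of variation).

``weibull3`` (WEI3, mean-parameterized Weibull)
    Classical Weibull with shape ``k = s`` and scale
    ``lambda = mu / Gamma(1 + 1/s)``, so that ``E(X) = mu`` exactly.  The
    coefficient of variation ``sqrt(Gamma(1+2/k)/Gamma(1+1/k)**2 - 1)``
    depends on the shape only.

``lognormal`` (LOGNO)
    ``log X ~ Normal(mu, s**2)``; here ``mu`` and ``s`` live on the log
    scale, so ``E(X) = exp(mu + s**2/2)``.

Densities, CDFs and quantiles delegate to the corresponding frozen
:mod:`scipy.stats` distributions; this module only owns the
reparameterizations and the moment inversions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

FAMILIES = ("gamma", "weibull3", "lognormal")

__all__ = [
    "FAMILIES",
    "DistParams",
    "pdf",
    "cdf",
    "sf",
    "quantile",
    "moments",
    "params_from_moments",
    "logpdf",
    "rvs",
]


@dataclass(frozen=True)
class DistParams:
    """Family tag plus the (mu, s) parameter pair.

    Both parameters must be strictly positive and finite; for the
    lognormal family they are the mean and SD of ``log X``.
    """

    family: str
    mu: float
    s: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not np.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu}")
        # The lognormal location lives on the log scale and may be negative;
        # for gamma and weibull3 the location is the mean and must be positive.
        if self.family != "lognormal" and not self.mu > 0:
            raise ValueError(f"mu must be positive for {self.family}, got {self.mu}")
        if not (np.isfinite(self.s) and self.s > 0):
            raise ValueError(f"s must be positive and finite, got {self.s}")

    def frozen(self):
        """The equivalent frozen scipy.stats distribution."""
        return _frozen(self.family, self.mu, self.s)


def _frozen(family: str, mu, s):
    mu = np.asarray(mu, dtype=float)
    s = np.asarray(s, dtype=float)
    if family == "gamma":
        return stats.gamma(a=1.0 / s**2, scale=s**2 * mu)
    if family == "weibull3":
        return stats.weibull_min(c=s, scale=mu / special.gamma(1.0 + 1.0 / s))
    if family == "lognormal":
        return stats.lognorm(s=s, scale=np.exp(mu))
    raise ValueError(f"unknown family {family!r}")


def _check_positive(x, name: str = "x") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError(f"{name} must be strictly positive")
    return x


def pdf(x, p: DistParams):
    """Density at ``x > 0``."""
    return p.frozen().pdf(_check_positive(x))


def logpdf(x, p: DistParams):
    return p.frozen().logpdf(_check_positive(x))


def cdf(x, p: DistParams):
    """P(X <= x) for ``x > 0``; strictly increasing on the support."""
    return p.frozen().cdf(_check_positive(x))


def sf(x, p: DistParams):
    """Survival function P(X > x)."""
    return p.frozen().sf(_check_positive(x))


def quantile(u, p: DistParams):
    """Inverse CDF at probabilities ``u`` in the open unit interval."""
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    return p.frozen().ppf(u)


def rvs(p: DistParams, size, rng: np.random.Generator):
    """Random draws using an explicit numpy Generator."""
    return p.frozen().rvs(size=size, random_state=rng)


def moments(p: DistParams) -> tuple[float, float]:
    """(mean, SD) of the distribution on its own scale.

    For gamma and weibull3 the mean is ``mu`` exactly; for lognormal the
    usual exp-formulas apply.
    """
    if p.family == "gamma":
        return p.mu, p.s * p.mu
    if p.family == "weibull3":
        return p.mu, p.mu * _weibull_cv(p.s)
    # lognormal
    m = np.exp(p.mu + p.s**2 / 2.0)
    sd = m * np.sqrt(np.expm1(p.s**2))
    return float(m), float(sd)


def _weibull_cv(shape: float) -> float:
    # log-gamma form stays finite for small shapes where Gamma overflows
    log_ratio = special.gammaln(1.0 + 2.0 / shape) - 2.0 * special.gammaln(1.0 + 1.0 / shape)
    return float(np.sqrt(np.expm1(log_ratio)))


def _weibull_shape_from_cv(cv: float) -> float:
    # CV is strictly decreasing in the shape; bracket then Brent.
    lo, hi = 1e-2, 1.0
    while _weibull_cv(hi) > cv:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError(f"coefficient of variation {cv} too small for Weibull")
    while _weibull_cv(lo) < cv:
        lo /= 2.0
        if lo < 1e-8:
            raise ValueError(f"coefficient of variation {cv} too large for Weibull")
    return float(optimize.brentq(lambda k: _weibull_cv(k) - cv, lo, hi, xtol=1e-13))


def params_from_moments(family: str, mean: float, sd: float) -> DistParams:
    """Invert (mean, SD) into DistParams for the given family.

    Round-trips with :func:`moments` to high precision.  For weibull3 the
    shape is recovered from the coefficient of variation by a bracketed
    one-dimensional root solve on the Gamma-function CV map.
    """
    if not (mean > 0 and sd > 0):
        raise ValueError("mean and sd must both be positive")
    cv = sd / mean
    if family == "gamma":
        return DistParams("gamma", mean, cv)
    if family == "weibull3":
        return DistParams("weibull3", mean, _weibull_shape_from_cv(cv))
    if family == "lognormal":
        sigma2 = np.log1p(cv**2)
        mu = np.log(mean) - sigma2 / 2.0
        return DistParams("lognormal", float(mu), float(np.sqrt(sigma2)))
    raise ValueError(f"unknown family {family!r}")
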