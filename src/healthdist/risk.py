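"""Tail-risk measures of health and percentile-bootstrap intervals.

The health score ``h`` lives on [0, 1] and is negatively skewed, so the
modelling happens on the reflected score ``h* = 1.0001 - h``, which is
positive and positively skewed.  A conditional distribution for ``h*``
implies, for any threshold ``t`` on the original scale,

    P(h <= t) = P(h* >= 1.0001 - t),

i.e. a survival probability of the transformed variable.  The three
standard thresholds are 0.8 ("average"), 0.7 ("fair") and 0.6 ("poor"),
roughly the 50th/30th/10th percentiles of the SF-6D score in a general
adult population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import families
from .families import DistParams

H0 = 1.0001  # reflection constant keeping h* strictly positive for h in [0, 1]

DEFAULT_THRESHOLDS = {"P_avg": 0.8, "P_fair": 0.7, "P_poor": 0.6}

logger = logging.getLogger(__name__)

__all__ = [
    "H0",
    "DEFAULT_THRESHOLDS",
    "RiskProfile",
    "transform",
    "inverse_transform",
    "risk_measures",
    "risk_from_values",
    "compare",
    "bootstrap_ci",
]


def transform(h):
    """Map health scores h in [0, 1] to the positive scale h* = 1.0001 - h."""
    h = np.asarray(h, dtype=float)
    if np.any((h < 0) | (h > 1)):
        raise ValueError("health scores must lie in [0, 1]")
    return H0 - h


def inverse_transform(h_star):
    """Inverse of :func:`transform`; accepts h* in [0.0001, 1.0001]."""
    h_star = np.asarray(h_star, dtype=float)
    if np.any((h_star < H0 - 1) | (h_star > H0)):
        raise ValueError(f"transformed scores must lie in [{H0 - 1}, {H0}]")
    return H0 - h_star


@dataclass
class RiskProfile:
    """Five distributional measures for one covariate profile.

    ``expected_health`` and ``sd_health`` describe the implied
    distribution of h; the P-measures are exceedance risks at the three
    thresholds.  ``ci`` maps measure names to (lower, upper) percentile
    bootstrap bounds when available.  ``source`` records which estimation
    route produced the profile (gamlss / empirical /
    parametric-from-quantiles).
    """

    expected_health: float
    sd_health: float
    measures: dict[str, float]
    source: str = "gamlss"
    family: str | None = "gamma"
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        data = {"E(h)": self.expected_health, "sigma": self.sd_health, **self.measures}
        return pd.Series(data, name=self.source)

    def __getitem__(self, key: str) -> float:
        if key == "E(h)":
            return self.expected_health
        if key == "sigma":
            return self.sd_health
        return self.measures[key]

    @property
    def measure_names(self) -> list[str]:
        return ["E(h)", "sigma", *self.measures.keys()]


def risk_measures(
    params: DistParams,
    thresholds: dict[str, float] | None = None,
    source: str = "gamlss",
) -> RiskProfile:
    """Risk profile implied by a fitted distribution of h* = 1.0001 - h.

    E(h) = 1.0001 - E(h*), sigma = SD(h*), and each P-measure is the h*
    survival probability at the reflected threshold.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    mean_star, sd_star = families.moments(params)
    measures = {
        name: float(families.sf(H0 - t, params)) for name, t in thresholds.items()
    }
    return RiskProfile(
        expected_health=float(H0 - mean_star),
        sd_health=float(sd_star),
        measures=measures,
        source=source,
        family=params.family,
    )


def risk_from_values(
    values,
    probs,
    thresholds: dict[str, float] | None = None,
) -> RiskProfile:
    """Risk profile read off a step-function CDF of h (empirical route).

    ``values``/``probs`` are the coordinates of a monotone empirical CDF
    (predicted quantiles against their probability levels); each
    P-measure is the largest probability whose quantile does not exceed
    the threshold.  The mean and SD are those of the discrete set of
    quantile predictions.
    """
    values = np.asarray(values, dtype=float)
    probs = np.asarray(probs, dtype=float)
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    measures = {}
    for name, t in thresholds.items():
        below = probs[values <= t]
        measures[name] = float(below.max()) if below.size else 0.0
    return RiskProfile(
        expected_health=float(values.mean()),
        sd_health=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        measures=measures,
        source="empirical",
        family=None,
    )


def compare(a: RiskProfile, b: RiskProfile) -> pd.DataFrame:
    """Contrast two profiles: absolute a-b and relative (a-b)/a in percent.

    Relative differences are computed from the unrounded values; a zero
    denominator yields NaN for that row.
    """
    rows = []
    for name in a.measure_names:
        va, vb = a[name], b[name]
        absolute = va - vb
        relative = np.nan if va == 0 else 100.0 * absolute / va
        rows.append((name, va, vb, absolute, relative))
    return pd.DataFrame(
        rows, columns=["measure", "a", "b", "absolute_diff", "relative_diff_pct"]
    ).set_index("measure")


def bootstrap_ci(
    table: pd.DataFrame,
    analysis,
    n_boot: int = 1000,
    seed: int = 0,
    max_failure_rate: float = 0.10,
):
    """Percentile bootstrap over individuals for a full-pipeline statistic.

    ``analysis`` maps a resampled person-level table to either a scalar, a
    dict of named scalars, or a :class:`RiskProfile`.  Individuals are
    resampled with replacement ``n_boot`` times; the 95% interval per
    measure is the (2.5th, 97.5th) percentile pair of the replicate
    values.  Replicates that raise are dropped and logged; more than
    ``max_failure_rate`` failures is an error.

    Returns ``(point, cis)`` where ``point`` is the analysis of the
    original table and ``cis`` maps measure names to (lower, upper).  If
    ``point`` is a RiskProfile its ``ci`` field is filled in place.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    point = analysis(table)
    n = len(table)
    replicates: list[dict[str, float]] = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resampled = table.iloc[idx].reset_index(drop=True)
        try:
            replicates.append(_as_measure_dict(analysis(resampled)))
        except Exception as exc:  # noqa: BLE001 - replicate-level robustness
            failures += 1
            logger.warning("bootstrap replicate failed: %s", exc)
    if failures > max_failure_rate * n_boot:
        raise RuntimeError(
            f"{failures}/{n_boot} bootstrap replicates failed "
            f"(limit {max_failure_rate:.0%})"
        )
    frame = pd.DataFrame(replicates)
    cis = {
        name: (
            float(np.percentile(frame[name], 2.5)),
            float(np.percentile(frame[name], 97.5)),
        )
        for name in frame.columns
    }
    point_values = _as_measure_dict(point)
    for name, (lo, hi) in cis.items():
        if not lo <= point_values[name] <= hi:
            logger.warning(
                "percentile CI for %s excludes the point estimate "
                "(%.4g outside [%.4g, %.4g])", name, point_values[name], lo, hi
            )
    if isinstance(point, RiskProfile):
        point.ci = cis
    return point, cis


def _as_measure_dict(result) -> dict[str, float]:
    if isinstance(result, RiskProfile):
        return {name: result[name] for name in result.measure_names}
    if isinstance(result, dict):
        return {k: float(v) for k, v in result.items()}
    return {"value": float(result)}
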