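"""Regression design for the survey table.

One fixed covariate layout is used by every model in the package:
log(equivalized income in $1000), age in years, a mean-centered squared
age term, the two children counts, life satisfaction on 0-10, and one
0/1 dummy per non-reference category of the seven lifestyle/demographic
factors.  With the intercept that is 27 columns.

The reference person — all dummies zero — is a non-indigenous
service & sales worker with fairly good sleep, frequent physical
activity, who does not smoke, is sometimes time-stressed, and is neither
satisfied nor dissatisfied with their weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORICAL_LEVELS",
    "REFERENCE_LEVELS",
    "NUMERIC_VARIABLES",
    "DesignSpec",
    "DesignMatrix",
    "CovariateProfile",
    "encode",
    "encode_profile",
    "reference_profile",
]

# Observed level sets, reference level first.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "ancestry": ("non_indigenous", "indigenous"),
    "occupation": (
        "service_sales",
        "managers_professionals",
        "manual",
        "unemployed",
        "not_in_labour_force",
    ),
    "smoking": ("no", "yes"),
    "sleep": ("fairly_good", "very_good", "fairly_bad", "very_bad", "not_reported"),
    "time_stress": ("sometimes", "almost_always", "often", "rarely", "never"),
    "weight_satisfaction": (
        "neither",
        "very_satisfied",
        "satisfied",
        "dissatisfied",
        "very_dissatisfied",
    ),
    "physical_activity": ("frequent", "none", "some"),
}

REFERENCE_LEVELS = {var: levels[0] for var, levels in CATEGORICAL_LEVELS.items()}

NUMERIC_VARIABLES = ("income", "age", "children_0_4", "children_5_14", "life_satisfaction")

# (design column, source variable, level) in display order; the intercept
# comes last, mirroring conventional coefficient tables.
_DUMMY_COLUMNS: tuple[tuple[str, str, str], ...] = (
    ("indigenous", "ancestry", "indigenous"),
    ("managers_professionals", "occupation", "managers_professionals"),
    ("manual", "occupation", "manual"),
    ("unemployed", "occupation", "unemployed"),
    ("not_in_labour_force", "occupation", "not_in_labour_force"),
    ("smoker", "smoking", "yes"),
    ("sleep_very_good", "sleep", "very_good"),
    ("sleep_fairly_bad", "sleep", "fairly_bad"),
    ("sleep_very_bad", "sleep", "very_bad"),
    ("sleep_not_reported", "sleep", "not_reported"),
    ("stress_almost_always", "time_stress", "almost_always"),
    ("stress_often", "time_stress", "often"),
    ("stress_rarely", "time_stress", "rarely"),
    ("stress_never", "time_stress", "never"),
    ("weight_very_satisfied", "weight_satisfaction", "very_satisfied"),
    ("weight_satisfied", "weight_satisfaction", "satisfied"),
    ("weight_dissatisfied", "weight_satisfaction", "dissatisfied"),
    ("weight_very_dissatisfied", "weight_satisfaction", "very_dissatisfied"),
    ("activity_none", "physical_activity", "none"),
    ("activity_some", "physical_activity", "some"),
)


@dataclass(frozen=True)
class DesignSpec:
    """Encoding rules: transforms, level sets and the age centering constant.

    ``age_center`` defaults to NaN meaning "recompute from the sample";
    :func:`encode` resolves it to the sample mean age so the squared term
    is orthogonal-ish to the linear one.
    """

    age_center: float = float("nan")
    categorical_levels: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(CATEGORICAL_LEVELS)
    )

    @property
    def reference_levels(self) -> dict[str, str]:
        return {var: levels[0] for var, levels in self.categorical_levels.items()}

    def resolved(self, table: pd.DataFrame) -> "DesignSpec":
        """Spec with the age center filled in from ``table`` if unset."""
        if np.isfinite(self.age_center):
            return self
        return replace(self, age_center=float(table["age"].mean()))


@dataclass
class DesignMatrix:
    """Encoded response and covariates.

    ``exog`` is an (n, 27) float array whose last column is the
    intercept; ``columns`` names the columns and ``column_kind`` tags each
    as numeric / dummy / intercept.
    """

    endog: np.ndarray
    exog: np.ndarray
    columns: list[str]
    column_kind: dict[str, str]
    spec: DesignSpec

    @property
    def nobs(self) -> int:
        return self.exog.shape[0]

    @property
    def ncols(self) -> int:
        return self.exog.shape[1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.exog, columns=self.columns)
        frame.insert(0, "health", self.endog)
        return frame


CovariateProfile = dict[str, float | str]


def _numeric_block(table: pd.DataFrame, spec: DesignSpec) -> dict[str, np.ndarray]:
    income = np.asarray(table["income"], dtype=float)
    if np.any(income <= 0):
        raise ValueError("income must be strictly positive (in $1000)")
    age = np.asarray(table["age"], dtype=float)
    return {
        "log_income": np.log(income),
        "age": age,
        "age_sq_centered": (age - spec.age_center) ** 2,
        "children_0_4": np.asarray(table["children_0_4"], dtype=float),
        "children_5_14": np.asarray(table["children_5_14"], dtype=float),
        "life_satisfaction": np.asarray(table["life_satisfaction"], dtype=float),
    }


def encode(table: pd.DataFrame, spec: DesignSpec | None = None) -> DesignMatrix:
    """Encode a survey table into the 27-column regression design.

    Raises on missing values, non-positive incomes, or category levels
    outside the spec's declared level sets (naming the offending rows).
    """
    spec = (spec or DesignSpec()).resolved(table)
    required = set(NUMERIC_VARIABLES) | set(spec.categorical_levels)
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"survey table is missing columns: {sorted(missing)}")
    if table[sorted(required)].isna().any().any():
        bad = table[sorted(required)].isna().any(axis=1)
        raise ValueError(f"missing values in rows {list(table.index[bad])[:10]}")

    cols = _numeric_block(table, spec)
    kind = {name: "numeric" for name in cols}
    for col_name, var, level in _DUMMY_COLUMNS:
        observed = table[var].astype(str)
        allowed = set(spec.categorical_levels[var])
        unseen = ~observed.isin(allowed)
        if unseen.any():
            row = int(np.flatnonzero(unseen.to_numpy())[0])
            raise ValueError(
                f"unseen level {observed.iloc[row]!r} for {var!r} at row {row}"
            )
        cols[col_name] = (observed == level).to_numpy(dtype=float)
        kind[col_name] = "dummy"
    cols["const"] = np.ones(len(table))
    kind["const"] = "intercept"

    endog = np.asarray(table["health"], dtype=float) if "health" in table else np.full(len(table), np.nan)
    exog = np.column_stack(list(cols.values()))
    return DesignMatrix(
        endog=endog,
        exog=exog,
        columns=list(cols.keys()),
        column_kind=kind,
        spec=spec,
    )


def encode_profile(profile: CovariateProfile, spec: DesignSpec) -> np.ndarray:
    """Expand one covariate profile into a single design row."""
    if not np.isfinite(spec.age_center):
        raise ValueError("spec.age_center must be resolved before encoding profiles")
    missing = (set(NUMERIC_VARIABLES) | set(spec.categorical_levels)) - set(profile)
    if missing:
        raise ValueError(f"profile is missing covariates: {sorted(missing)}")
    frame = pd.DataFrame([profile])
    return encode(frame, spec).exog[0]


def reference_profile(
    spec: DesignSpec,
    table: pd.DataFrame,
    overrides: CovariateProfile | None = None,
) -> CovariateProfile:
    """Counterfactual profile: numeric covariates at sample means,
    categoricals at reference levels, then overrides applied.

    Non-integer means for the count variables are intentional — the
    profile is a population-average construct, not an actual person.
    """
    profile: CovariateProfile = {
        var: float(table[var].mean()) for var in NUMERIC_VARIABLES
    }
    profile.update(spec.reference_levels)
    for key, value in (overrides or {}).items():
        if key not in profile:
            raise ValueError(f"unknown covariate {key!r} in overrides")
        profile[key] = value
    return profile
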