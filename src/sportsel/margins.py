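"""Marginal models: probit participation and Gamma aggregate duration.

The participation propensity is latent normal with unit variance, so
``P(participate) = Phi(x'beta)``.  Aggregate duration over a 28-day window
is Gamma with scale ``lambda = exp(x'gamma)`` and shape ``alpha * q`` where
``q`` is the respondent's event multiplicity: per-event durations are iid
Gamma(alpha, lambda) and the Gamma family is closed under addition.

Design vectors are resolved by name from :class:`CovariateProfile` maps so
that the participation and duration covariate sets can differ (neither
nests the other).  All durations are hours per 28 days internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "DesignError",
    "CovariateProfile",
    "ParticipationMargin",
    "DurationMargin",
    "linear_predictor",
    "participation_prob",
    "duration_cdf",
    "duration_pdf",
    "duration_logpdf",
    "duration_ppf",
    "PARTICIPATION_COVARIATES",
    "DURATION_COVARIATES",
    "read_coefficients_csv",
    "write_coefficients_csv",
]

CONSTANT = "constant"

#: default participation design, in the packaged reporting row order
#: (intercept first; reference groups implicit).
PARTICIPATION_COVARIATES = [
    CONSTANT,
    "gender_male",
    "age_16_24",
    "age_25_34",
    "age_35_44",
    "age_45_54",
    "ln_income",
    "single",
    "divorced_sep_widowed",
    "n_children_2_15",
    "n_children_under_2",
    "mother_alive",
    "tv_hours_week",
    "car_available",
    "no_education",
    "retired",
    "unemployed",
    "inactive",
    "health_very_good",
    "health_good",
    "health_fair",
    "wellbeing_good",
    "wellbeing_fair",
    "wellbeing_missing",
    "accident",
    "area_sport_hours",
    "area_bmi",
    "smoker",
    "ex_smoker",
    "drinker_under_limit",
    "drinker_over_limit",
    "diet_score",
]

#: default duration design; long-standing illness and vigour enter only here,
#: while income/education/car/wellbeing/accident/area enter only above.
DURATION_COVARIATES = [
    CONSTANT,
    "gender_male",
    "age_16_24",
    "age_25_34",
    "age_35_44",
    "age_45_54",
    "single",
    "divorced_sep_widowed",
    "n_children_2_15",
    "n_children_under_2",
    "mother_alive",
    "tv_hours_week",
    "retired",
    "unemployed",
    "inactive",
    "health_very_good",
    "health_good",
    "health_fair",
    "illness_limiting",
    "illness_non_limiting",
    "smoker",
    "ex_smoker",
    "drinker_under_limit",
    "drinker_over_limit",
    "diet_score",
    "vigour_moderate",
    "vigour_high",
]


class DesignError(KeyError):
    """A design name cannot be resolved in the supplied profile/table."""


@dataclass(frozen=True)
class CovariateProfile:
    """Named covariate values; the implicit ``constant`` resolves to 1."""

    values: Mapping[str, float]

    def vector(self, names: Sequence[str]) -> np.ndarray:
        missing = [n for n in names if n != CONSTANT and n not in self.values]
        if missing:
            raise DesignError(f"profile is missing covariates: {missing}")
        out = np.array(
            [1.0 if n == CONSTANT else float(self.values[n]) for n in names]
        )
        if not np.all(np.isfinite(out)):
            bad = [n for n, x in zip(names, out) if not np.isfinite(x)]
            raise DesignError(f"non-finite covariate values for: {bad}")
        return out


def design_matrix(table: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    """Build an (n, k) design matrix from a covariate table by column name."""
    missing = [n for n in names if n != CONSTANT and n not in table.columns]
    if missing:
        raise DesignError(f"covariate table is missing columns: {missing}")
    cols = [
        np.ones(len(table)) if n == CONSTANT else table[n].to_numpy(dtype=float)
        for n in names
    ]
    return np.column_stack(cols)


@dataclass(frozen=True)
class ParticipationMargin:
    """Probit participation margin with coefficients ``beta``."""

    beta: np.ndarray
    names: Sequence[str] = field(default_factory=lambda: list(PARTICIPATION_COVARIATES))

    def __post_init__(self):
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if self.beta.shape != (len(self.names),):
            raise DesignError(
                f"beta has length {self.beta.shape[0]}, design has {len(self.names)} names"
            )


@dataclass(frozen=True)
class DurationMargin:
    """Gamma duration margin: coefficients ``gamma`` and per-event shape ``alpha``."""

    gamma: np.ndarray
    alpha: float
    names: Sequence[str] = field(default_factory=lambda: list(DURATION_COVARIATES))

    def __post_init__(self):
        object.__setattr__(self, "gamma", np.asarray(self.gamma, dtype=float))
        if self.gamma.shape != (len(self.names),):
            raise DesignError(
                f"gamma has length {self.gamma.shape[0]}, design has {len(self.names)} names"
            )
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")


def linear_predictor(profile: CovariateProfile, names: Sequence[str], coefs) -> float:
    return float(profile.vector(names) @ np.asarray(coefs, dtype=float))


def participation_prob(profile: CovariateProfile, margin: ParticipationMargin) -> float:
    """``P(S = 1) = Phi(x'beta)`` for the given profile."""
    return float(stats.norm.cdf(linear_predictor(profile, margin.names, margin.beta)))


def _shape_scale(t, q, profile: CovariateProfile, margin: DurationMargin):
    t = np.asarray(t, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(t <= 0):
        raise ValueError("duration t must be > 0")
    if np.any(q < 1):
        raise ValueError("multiplicity q must be >= 1")
    lam = np.exp(linear_predictor(profile, margin.names, margin.gamma))
    return t, margin.alpha * q, lam


def duration_cdf(t, q, profile: CovariateProfile, margin: DurationMargin):
    """Aggregate-duration cdf ``G(t) = 1 - Gamma(alpha q, t/lambda)/Gamma(alpha q)``
    (one minus the regularized upper incomplete gamma)."""
    t, shape, lam = _shape_scale(t, q, profile, margin)
    return 1.0 - special.gammaincc(shape, t / lam)


def duration_pdf(t, q, profile: CovariateProfile, margin: DurationMargin):
    t, shape, lam = _shape_scale(t, q, profile, margin)
    return stats.gamma.pdf(t, a=shape, scale=lam)


def duration_logpdf(t, q, profile: CovariateProfile, margin: DurationMargin):
    t, shape, lam = _shape_scale(t, q, profile, margin)
    return stats.gamma.logpdf(t, a=shape, scale=lam)


def duration_ppf(p, q, profile: CovariateProfile, margin: DurationMargin):
    """Quantile function of the aggregate-duration distribution."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie in (0, 1)")
    q = np.asarray(q, dtype=float)
    lam = np.exp(linear_predictor(profile, margin.names, margin.gamma))
    return special.gammaincinv(margin.alpha * q, p) * lam


def duration_mean(q, profile: CovariateProfile, margin: DurationMargin) -> float:
    """``E[T] = alpha q lambda``."""
    lam = np.exp(linear_predictor(profile, margin.names, margin.gamma))
    return float(margin.alpha * np.asarray(q, dtype=float) * lam)


def read_coefficients_csv(path) -> pd.DataFrame:
    """Read a coefficient table with columns (margin, name, estimate, std_error)."""
    df = pd.read_csv(path)
    required = {"margin", "name", "estimate"}
    if not required.issubset(df.columns):
        raise DesignError(f"{path}: expected columns {sorted(required)}")
    return df


def write_coefficients_csv(df: pd.DataFrame, path) -> None:
    cols = ["margin", "name", "estimate", "std_error"]
    df.reindex(columns=cols).to_csv(path, index=False)
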