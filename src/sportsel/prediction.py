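"""Conditional and marginal mean-duration predictions and the BMI analysis.

Under independence the mean duration among participants equals the
unconditional mean ``alpha q lambda``.  Under Frank dependence the
conditional mean is

    E[T* | S* > 0] = Phi(x'beta)^{-1} (alpha q lambda - I),
    I = int_0^inf t * (1 - e^{theta C}) / (1 - e^{theta G}) * g(t) dt,

with ``C = C_theta(F(0), G(t))``; the integral is evaluated by adaptive
quadrature after the substitution ``v = G(t)``.  A conditional-inversion
Monte-Carlo estimator is provided as an independent cross-check.

Internal durations are hours per 28 days; weekly figures are the 28-day
values divided by four, and per-week event counts are multiplied by four
on the way in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import integrate, special, stats

from .copulas import frank_cdf, sample_pairs, _phi_ratio
from .margins import CovariateProfile, DesignError, linear_predictor
from .selection_model import ModelParams

__all__ = [
    "Scenario",
    "BmiModel",
    "VIGOUR_LEVELS",
    "marginal_mean_duration",
    "conditional_mean_duration",
    "mc_conditional_mean",
    "bmi_predict",
]

VIGOUR_LEVELS = ("low", "moderate", "high")

#: BMI regressor order: constant, demographics, lifestyle, participation and
#: the three duration-by-vigour interactions (duration in hours/week).
BMI_REGRESSORS = [
    "constant",
    "gender_male",
    "age_16_24",
    "age_25_34",
    "age_35_44",
    "age_45_54",
    "ln_income",
    "ex_smoker",
    "smoker",
    "drinker_over_limit",
    "drinker_under_limit",
    "diet_score",
    "participation",
    "duration_low_vigour",
    "duration_moderate_vigour",
    "duration_high_vigour",
]


@dataclass(frozen=True)
class Scenario:
    """A covariate profile plus multiplicity and vigour setting.

    ``q_events_28d`` counts events per 28 days (a per-week count is four
    times smaller).  The vigour setting activates at most one of the two
    duration-design vigour dummies (low is the reference).
    """

    profile: CovariateProfile
    q_events_28d: float
    vigour: str = "low"

    def __post_init__(self):
        if self.q_events_28d <= 0:
            raise ValueError("q_events_28d must be positive")
        if self.vigour not in VIGOUR_LEVELS:
            raise ValueError(f"vigour must be one of {VIGOUR_LEVELS}")

    def duration_profile(self) -> CovariateProfile:
        values = dict(self.profile.values)
        values["vigour_moderate"] = 1.0 if self.vigour == "moderate" else 0.0
        values["vigour_high"] = 1.0 if self.vigour == "high" else 0.0
        return CovariateProfile(values)


def _margin_quantities(scenario: Scenario, params: ModelParams):
    xb = linear_predictor(
        scenario.profile, params.participation.names, params.participation.beta
    )
    lam = np.exp(
        linear_predictor(
            scenario.duration_profile(), params.duration.names, params.duration.gamma
        )
    )
    shape = params.duration.alpha * scenario.q_events_28d
    return xb, shape, lam


def marginal_mean_duration(scenario: Scenario, params: ModelParams) -> float:
    """Unconditional mean ``E[T*] = alpha q lambda`` in hours per 28 days."""
    _, shape, lam = _margin_quantities(scenario, params)
    return float(shape * lam)


def conditional_mean_duration(
    scenario: Scenario, params: ModelParams, rel_tol: float = 1e-8
) -> float:
    """``E[T* | S* > 0]`` in hours per 28 days, by quadrature on v = G(t)."""
    xb, shape, lam = _margin_quantities(scenario, params)
    Phi = float(stats.norm.cdf(xb))
    if Phi <= 0.0:
        raise ValueError("participation probability is zero for this scenario")
    mean = shape * lam
    dep = params.dependence
    if params.family == "independence" or dep.is_independent:
        return float(mean)

    F0 = float(np.clip(1.0 - Phi, 1e-14, 1.0 - 1e-14))

    def integrand(v):
        t = special.gammaincinv(shape, v) * lam
        C = frank_cdf(F0, v, dep)
        return t * _phi_ratio(np.clip(C, 1e-300, None), v, dep)

    I, err = integrate.quad(
        integrand, 0.0, 1.0, epsrel=rel_tol, epsabs=1e-12, limit=400
    )
    if not np.isfinite(I) or (abs(I) > 0 and err / max(abs(I), 1e-300) > 1e-4):
        # fallback: fixed high-order Gauss-Legendre with a refinement check
        for nodes in (401, 801):
            x, w = np.polynomial.legendre.leggauss(nodes)
            v = 0.5 * (x + 1.0)
            I_new = 0.5 * float(w @ integrand(v))
            if nodes > 401 and abs(I_new - I) > 1e-6 * max(abs(I_new), 1.0):
                raise FloatingPointError(
                    f"quadrature did not converge (delta {abs(I_new - I):.3g})"
                )
            I = I_new
    return float((mean - I) / Phi)


def mc_conditional_mean(
    scenario: Scenario, params: ModelParams, n_draws: int = 10**6, seed=0
) -> tuple[float, float]:
    """Monte-Carlo estimate of ``E[T* | S* > 0]`` with its standard error.

    Draws ``(u, v)`` pairs from the copula, keeps pairs with ``u > F(0)``
    (the participation event) and averages the duration quantile at ``v``.
    """
    if n_draws < 10**4:
        raise ValueError("n_draws must be at least 10^4")
    xb, shape, lam = _margin_quantities(scenario, params)
    F0 = float(stats.norm.cdf(-xb))
    uv = sample_pairs(params.dependence, n_draws, seed)
    keep = uv[:, 0] > F0
    if not keep.any():
        raise ValueError("no draws fell in the participation region; increase n_draws")
    v = np.clip(uv[keep, 1], 1e-15, 1.0 - 1e-15)
    t = special.gammaincinv(shape, v) * lam
    est = float(t.mean())
    se = float(t.std(ddof=1) / np.sqrt(t.size))
    return est, se


@dataclass(frozen=True)
class BmiModel:
    """Linear BMI model over the packaged regressor list."""

    coefficients: Mapping[str, float]

    def __post_init__(self):
        missing = [n for n in BMI_REGRESSORS if n not in self.coefficients]
        if missing:
            raise DesignError(f"BMI model is missing coefficients: {missing}")


def bmi_predict(
    model: BmiModel,
    profile: CovariateProfile,
    participation: int,
    duration_hours_week: float,
    vigour: str,
) -> float:
    """Pure linear predictor of BMI; the duration (hours/week) interacts
    only with the active vigour level."""
    if vigour not in VIGOUR_LEVELS:
        raise ValueError(f"vigour must be one of {VIGOUR_LEVELS}")
    coefs = model.coefficients
    value = coefs["constant"]
    for name in BMI_REGRESSORS:
        if name == "constant" or name.startswith("duration_") or name == "participation":
            continue
        if name not in profile.values:
            raise DesignError(f"profile is missing BMI regressor {name!r}")
        value += coefs[name] * float(profile.values[name])
    value += coefs["participation"] * participation
    value += coefs[f"duration_{vigour}_vigour"] * duration_hours_week
    return float(value)
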