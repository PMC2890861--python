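"""Frank copula family with the independence (Product) limit.

The Frank family is the only Archimedean family implemented here; the
generator-based quantities are exposed because the selection likelihood is
written in terms of the generator derivative.  The dependence parameter
``theta`` is any real number: positive values give positive association,
negative values negative association, and the ``theta -> 0`` limit is the
Product copula ``C(u, v) = u v``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "FrankDependence",
    "frank_cdf",
    "generator_derivative",
    "conditional_cdf",
    "conditional_inverse",
    "kendall_tau",
    "kendall_tau_inverse",
    "sample_pairs",
]

#: below this |theta| the Product-copula branch is used (the Frank closed
#: form is 0/0 at theta = 0).
THETA_INDEPENDENCE = 1e-8

#: hard guard against overflow in exp(theta * .) terms; tau(35) > 0.88, so
#: the family is effectively comonotone long before the guard engages.
THETA_MAX_ABS = 35.0


@dataclass(frozen=True)
class FrankDependence:
    """Dependence parameter of the Frank copula family."""

    theta: float

    def __post_init__(self) -> None:
        th = float(self.theta)
        if not np.isfinite(th):
            raise ValueError(f"theta must be finite, got {self.theta!r}")
        if abs(th) > THETA_MAX_ABS:
            raise ValueError(
                f"|theta| = {abs(th):g} exceeds the overflow guard "
                f"{THETA_MAX_ABS:g}"
            )

    @property
    def is_independent(self) -> bool:
        return abs(self.theta) < THETA_INDEPENDENCE


def _check_unit(name: str, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any((x < 0.0) | (x > 1.0)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return x


def frank_cdf(u, v, dep: FrankDependence):
    """Copula cdf ``C_theta(u, v)``; vectorized over ``u`` and ``v``.

    Uses the expm1/log1p form ``-(1/theta) * log1p(expm1(-theta u)
    * expm1(-theta v) / expm1(-theta))`` which is stable on the whole
    guarded theta range.
    """
    u = _check_unit("u", u)
    v = _check_unit("v", v)
    if dep.is_independent:
        return u * v
    th = dep.theta
    num = np.expm1(-th * u) * np.expm1(-th * v) / np.expm1(-th)
    with np.errstate(divide="ignore"):
        c = -np.log1p(num) / th
    # clamp tiny negative round-off at the lower Frechet bound
    return np.clip(c, 0.0, np.minimum(u, v))


def generator_derivative(r, dep: FrankDependence):
    """Derivative ``phi'(r) = theta / (1 - exp(theta r))`` of the Frank
    Archimedean generator; strictly negative on (0, 1].

    ``r = 0`` is the singular boundary of the generator and is rejected.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0.0) or np.any(r > 1.0):
        raise ValueError("r must lie in (0, 1]; r = 0 is singular")
    if dep.is_independent:
        # phi(r) = -log r for the Product copula
        return -1.0 / r
    th = dep.theta
    return -th / np.expm1(th * r)


def _phi_ratio(c, v, dep: FrankDependence):
    """phi'(v) / phi'(C) = expm1(theta C) / expm1(theta v), computed without
    validation (internal; c, v in (0,1], c <= relevant bound)."""
    if dep.is_independent:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.asarray(c, float) / np.asarray(v, float)
    th = dep.theta
    return np.expm1(th * np.asarray(c, float)) / np.expm1(th * np.asarray(v, float))


def conditional_cdf(u, v, dep: FrankDependence):
    """Conditional distribution ``P(V <= v | U = u) = dC(u, v)/du``.

    Closed form: ``e^{-theta u} (e^{-theta v} - 1) /
    [(e^{-theta} - 1) + (e^{-theta u} - 1)(e^{-theta v} - 1)]``.
    """
    u = _check_unit("u", u)
    v = _check_unit("v", v)
    if dep.is_independent:
        return np.broadcast_to(v, np.broadcast_shapes(u.shape, v.shape)).copy()
    th = dep.theta
    a = np.expm1(-th * u)
    b = np.expm1(-th * v)
    return (a + 1.0) * b / (np.expm1(-th) + a * b)


def conditional_inverse(u, p, dep: FrankDependence):
    """Inverse of :func:`conditional_cdf` in ``v``: the ``p``-quantile of
    ``V`` given ``U = u``.  Used by the conditional-inversion sampler."""
    u = _check_unit("u", u)
    p = _check_unit("p", p)
    if dep.is_independent:
        return np.broadcast_to(p, np.broadcast_shapes(u.shape, p.shape)).copy()
    th = dep.theta
    denom = np.exp(-th * u) * (1.0 - p) + p
    return -np.log1p(p * np.expm1(-th) / denom) / th


def _debye1(theta: float) -> float:
    """First Debye function ``D1(theta) = (1/theta) int_0^theta s/(e^s - 1) ds``
    by adaptive quadrature (relative tolerance 1e-10); valid for both signs."""

    def integrand(s):
        s = np.asarray(s, dtype=float)
        out = np.ones_like(s)
        nz = s != 0.0
        out[nz] = s[nz] / np.expm1(s[nz])
        return out

    val, _ = integrate.quad(integrand, 0.0, theta, epsrel=1e-10, epsabs=1e-13, limit=200)
    return val / theta


def kendall_tau(dep: FrankDependence) -> float:
    """Kendall rank correlation ``tau(theta) = 1 - (4/theta)(1 - D1(theta))``."""
    if dep.is_independent:
        return 0.0
    th = dep.theta
    return 1.0 - 4.0 / th * (1.0 - _debye1(th))


def kendall_tau_inverse(tau0: float) -> FrankDependence:
    """Solve ``tau(theta) = tau0`` for theta (monotone bisection).

    Useful for dependence starting values.  ``tau0`` must be attainable
    within the guarded theta range.
    """
    if not np.isfinite(tau0) or abs(tau0) >= 1.0:
        raise ValueError("tau0 must lie in (-1, 1)")
    if abs(tau0) < 1e-12:
        return FrankDependence(0.0)
    lo, hi = -THETA_MAX_ABS, THETA_MAX_ABS
    tau_hi = kendall_tau(FrankDependence(hi))
    if abs(tau0) > tau_hi:
        raise ValueError(
            f"|tau0| = {abs(tau0):g} not attainable with |theta| <= {THETA_MAX_ABS:g}"
        )
    theta = optimize.brentq(
        lambda th: kendall_tau(FrankDependence(th)) - tau0, lo, hi, xtol=1e-12
    )
    return FrankDependence(theta)


def sample_pairs(dep: FrankDependence, n: int, seed) -> np.ndarray:
    """Draw ``n`` pairs ``(u, v)`` from the copula by conditional inversion.

    ``seed`` may be an int or a ``numpy.random.Generator``.  Returns an
    ``(n, 2)`` array with uniform margins and the Frank dependence.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.uniform(size=n)
    p = rng.uniform(size=n)
    v = conditional_inverse(u, p, dep)
    return np.column_stack([u, v])
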