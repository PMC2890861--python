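"""Joint selection model: probit participation, Gamma duration, Frank copula.

Observation rules: participation ``S = 1{S* > 0}`` and duration
``T = 1{S* > 0} T*`` — duration is observed only for participants.  With
``F`` the participation-propensity cdf (so ``F(0) = 1 - Phi(x'beta)``),
``G``/``g`` the duration cdf/pdf, and ``phi`` the Archimedean generator of
the copula, the likelihood is

    L = prod_{s=0} F(0) * prod_{s=1} (1 - phi'(G) / phi'(C_theta(F(0), G))) g(t)

For the Frank family ``phi'(G)/phi'(C) = expm1(theta C)/expm1(theta G)``;
in the ``theta -> 0`` limit the participant weight becomes ``Phi(x'beta)``
and the likelihood factorizes into a probit plus a Gamma regression.

Estimation is by quasi-Newton maximum likelihood on the unconstrained
parameterization (beta, gamma, log alpha, theta) with central-difference
gradients; standard errors come from the inverse observed information
(numerically differentiated Hessian).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .copulas import (
    THETA_INDEPENDENCE,
    FrankDependence,
    frank_cdf,
    kendall_tau,
    _phi_ratio,
)
from .margins import (
    DURATION_COVARIATES,
    PARTICIPATION_COVARIATES,
    DesignError,
    DurationMargin,
    ParticipationMargin,
    design_matrix,
)

__all__ = [
    "SelectionDataset",
    "ModelParams",
    "FitResult",
    "LikelihoodError",
    "ConvergenceError",
    "log_likelihood",
    "fit",
    "standard_errors",
    "lr_test",
    "likelihood_ratio",
]

logger = logging.getLogger(__name__)

FAMILIES = ("frank", "independence")

# bounds for the unconstrained optimizer; theta stays inside the copula
# overflow guard, log(alpha) spans (4.5e-5, 2.2e4)
_THETA_BOUND = 30.0
_LOG_ALPHA_BOUND = 10.0
_COEF_BOUND = 60.0


class LikelihoodError(FloatingPointError):
    """A likelihood contribution is non-finite at the requested parameters."""


class ConvergenceError(RuntimeError):
    """The optimizer failed; carries the best iterate found."""

    def __init__(self, message, best=None, grad_norm=None):
        super().__init__(message)
        self.best = best
        self.grad_norm = grad_norm


@dataclass
class SelectionDataset:
    """Aligned arrays for one estimation sample.

    ``t`` and ``q`` are NaN for non-participants; participants must have
    ``t > 0`` and ``q >= 1``.
    """

    s: np.ndarray
    t: np.ndarray
    q: np.ndarray
    X_part: np.ndarray
    X_dur: np.ndarray
    part_names: Sequence[str] = field(default_factory=lambda: list(PARTICIPATION_COVARIATES))
    dur_names: Sequence[str] = field(default_factory=lambda: list(DURATION_COVARIATES))
    n_dropped_zero_duration: int = 0

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.X_part = np.asarray(self.X_part, dtype=float)
        self.X_dur = np.asarray(self.X_dur, dtype=float)
        n = self.s.shape[0]
        if not (self.t.shape[0] == self.q.shape[0] == n == self.X_part.shape[0] == self.X_dur.shape[0]):
            raise ValueError("all dataset components must share the same length")
        if not np.all(np.isin(self.s, (0, 1))):
            raise ValueError("s must be 0/1")
        part = self.s == 1
        if np.any(~np.isfinite(self.t[part])) or np.any(self.t[part] <= 0):
            raise ValueError("participants must have finite t > 0")
        if np.any(~np.isfinite(self.q[part])) or np.any(self.q[part] < 1):
            raise ValueError("participants must have q >= 1")
        if not (np.all(np.isfinite(self.X_part)) and np.all(np.isfinite(self.X_dur))):
            raise DesignError("covariate matrices contain non-finite values")
        if self.X_part.shape[1] != len(self.part_names):
            raise DesignError("participation design width does not match its names")
        if self.X_dur.shape[1] != len(self.dur_names):
            raise DesignError("duration design width does not match its names")

    @property
    def n(self) -> int:
        return int(self.s.shape[0])

    @property
    def n1(self) -> int:
        return int(self.s.sum())

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        part_names: Sequence[str] = None,
        dur_names: Sequence[str] = None,
        drop_zero_durations: bool = True,
    ) -> "SelectionDataset":
        """Build a dataset from a flat table with columns ``s``, ``t``, ``q``
        plus all design covariates (vigour already coded as dummies).

        Participants reporting zero duration cannot enter the Gamma margin;
        with ``drop_zero_durations`` they are removed with a logged count.
        """
        part_names = list(part_names or PARTICIPATION_COVARIATES)
        dur_names = list(dur_names or DURATION_COVARIATES)
        tab = table
        bad = (tab["s"] == 1) & ~(tab["t"] > 0)
        if bad.any():
            if not drop_zero_durations:
                raise ValueError(f"{int(bad.sum())} participant rows have t <= 0")
            logger.info("dropping %d zero-duration participant row(s)", int(bad.sum()))
            tab = tab.loc[~bad]
        return cls(
            s=tab["s"].to_numpy(),
            t=tab["t"].to_numpy(dtype=float),
            q=tab["q"].to_numpy(dtype=float),
            X_part=design_matrix(tab, part_names),
            X_dur=design_matrix(tab, dur_names),
            part_names=part_names,
            dur_names=dur_names,
            n_dropped_zero_duration=int(bad.sum()),
        )


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set (beta, gamma, alpha, theta) with a family tag."""

    participation: ParticipationMargin
    duration: DurationMargin
    dependence: FrankDependence
    family: str = "frank"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.family == "independence" and abs(self.dependence.theta) >= THETA_INDEPENDENCE:
            raise ValueError("independence family requires theta at the Product branch")


def _pack(params: ModelParams) -> np.ndarray:
    vec = np.concatenate(
        [
            params.participation.beta,
            params.duration.gamma,
            [np.log(params.duration.alpha)],
        ]
    )
    if params.family == "frank":
        vec = np.append(vec, params.dependence.theta)
    return vec


def _unpack(vec: np.ndarray, data: SelectionDataset, family: str) -> ModelParams:
    k0 = len(data.part_names)
    k1 = len(data.dur_names)
    beta = vec[:k0]
    gamma = vec[k0 : k0 + k1]
    alpha = float(np.exp(vec[k0 + k1]))
    theta = float(vec[k0 + k1 + 1]) if family == "frank" else 0.0
    return ModelParams(
        participation=ParticipationMargin(beta, data.part_names),
        duration=DurationMargin(gamma, alpha, data.dur_names),
        dependence=FrankDependence(theta),
        family=family,
    )


def log_likelihood(params: ModelParams, data: SelectionDataset) -> float:
    """Total log-likelihood; raises :class:`LikelihoodError` (with the
    offending respondent indices) on non-finite contributions."""
    contrib = _contributions(params, data)
    if not np.all(np.isfinite(contrib)):
        bad = np.flatnonzero(~np.isfinite(contrib))
        raise LikelihoodError(
            f"non-finite log-likelihood contribution at respondent indices {bad[:10].tolist()}"
        )
    return float(contrib.sum())


def _contributions(params: ModelParams, data: SelectionDataset) -> np.ndarray:
    xb = data.X_part @ params.participation.beta
    out = np.empty(data.n)
    nonpart = data.s == 0
    # log F(0) = log(1 - Phi(x'beta)) = Phi(-x'beta)
    out[nonpart] = stats.norm.logcdf(-xb[nonpart])

    part = ~nonpart
    if part.any():
        t = data.t[part]
        shape = params.duration.alpha * data.q[part]
        lam = np.exp(data.X_dur[part] @ params.duration.gamma)
        log_g = stats.gamma.logpdf(t, a=shape, scale=lam)
        if params.family == "independence" or params.dependence.is_independent:
            log_w = stats.norm.logcdf(xb[part])
        else:
            F0 = stats.norm.cdf(-xb[part])
            G = 1.0 - special.gammaincc(shape, t / lam)
            # keep strictly inside (0,1) so the generator terms stay regular
            eps = 1e-14
            F0 = np.clip(F0, eps, 1.0 - eps)
            G = np.clip(G, 1e-300, 1.0 - eps)
            C = frank_cdf(F0, G, params.dependence)
            C = np.clip(C, 1e-300, None)
            weight = 1.0 - _phi_ratio(C, G, params.dependence)
            with np.errstate(divide="ignore"):
                log_w = np.log(weight)
        out[part] = log_w + log_g
    return out


def _central_gradient(f, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(x.size):
        h = rel_step * max(1.0, abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2.0 * h)
    return g


def _central_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x.copy()
                xm = x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp = x.copy(); xpm = x.copy(); xmp = x.copy(); xmm = x.copy()
                xpp[[i, j]] += [h[i], h[j]]
                xpm[i] += h[i]; xpm[j] -= h[j]
                xmp[i] -= h[i]; xmp[j] += h[j]
                xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                    4.0 * h[i] * h[j]
                )
    return H


@dataclass
class FitResult:
    """Maximum-likelihood estimates with observed-information standard errors."""

    params: ModelParams
    loglik: float
    se: dict
    cov: np.ndarray
    converged: bool
    n_iter: int
    grad_norm: float
    n: int
    n1: int
    tau: Optional[float] = None
    tau_se: Optional[float] = None
    hessian_pd: bool = True
    loglik_trace: list = field(default_factory=list)

    def coefficient_frame(self) -> pd.DataFrame:
        """Coefficient table in the packaged reporting row order."""
        rows = []
        p = self.params
        for name, est in zip(p.participation.names, p.participation.beta):
            rows.append(("participation", name, est, self.se.get(("participation", name))))
        for name, est in zip(p.duration.names, p.duration.gamma):
            rows.append(("duration", name, est, self.se.get(("duration", name))))
        rows.append(("duration", "alpha", p.duration.alpha, self.se.get(("duration", "alpha"))))
        if p.family == "frank":
            rows.append(("copula", "theta", p.dependence.theta, self.se.get(("copula", "theta"))))
            rows.append(("copula", "kendall_tau", self.tau, self.tau_se))
        return pd.DataFrame(rows, columns=["margin", "name", "estimate", "std_error"])

    def to_json(self) -> str:
        p = self.params
        payload = {
            "family": p.family,
            "loglik": self.loglik,
            "n": self.n,
            "n1": self.n1,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
            "hessian_pd": self.hessian_pd,
            "alpha": p.duration.alpha,
            "theta": p.dependence.theta,
            "tau": self.tau,
            "tau_se": self.tau_se,
            "beta": dict(zip(p.participation.names, p.participation.beta.tolist())),
            "gamma": dict(zip(p.duration.names, p.duration.gamma.tolist())),
        }
        return json.dumps(payload, indent=2)


def _probit_start(data: SelectionDataset) -> np.ndarray:
    import statsmodels.api as sm

    model = sm.Probit(data.s, data.X_part)
    try:
        res = model.fit(disp=0, maxiter=200)
        return np.asarray(res.params, dtype=float)
    except Exception:  # fall back to zeros; the joint optimizer will recover
        return np.zeros(data.X_part.shape[1])


def _gamma_start(data: SelectionDataset) -> tuple[np.ndarray, float]:
    part = data.s == 1
    y = np.log(data.t[part] / data.q[part])
    X = data.X_dur[part]
    gamma, *_ = np.linalg.lstsq(X, y, rcond=None)
    return gamma, 1.0


def _theta_start(data: SelectionDataset, beta: np.ndarray) -> float:
    from .copulas import kendall_tau_inverse

    part = data.s == 1
    if part.sum() < 10:
        return 0.5
    propensity = (data.X_part @ beta)[part]
    tau_hat, _ = stats.kendalltau(propensity, data.t[part])
    tau_hat = float(np.clip(np.nan_to_num(tau_hat), -0.8, 0.8))
    if abs(tau_hat) < 1e-3:
        return 0.1
    return kendall_tau_inverse(tau_hat).theta


def _best_theta_start(data: SelectionDataset, x_margins: np.ndarray, theta0: float) -> float:
    """Profile the likelihood over a coarse theta grid at fixed margins; the
    rank-based start alone can sit on the wrong side of zero because the
    selection effect distorts the participant ranks."""
    candidates = sorted({-8.0, -3.0, -1.0, 0.5, 1.0, 3.0, 8.0, float(theta0)})
    best_theta, best_ll = theta0, -np.inf
    for th in candidates:
        try:
            params = _unpack(np.append(x_margins, th), data, "frank")
            ll = log_likelihood(params, data)
        except (LikelihoodError, ValueError):
            continue
        if ll > best_ll:
            best_theta, best_ll = th, ll
    return best_theta


def fit(
    data: SelectionDataset,
    family: str = "frank",
    start: Optional[ModelParams] = None,
    gtol: float = 1e-6,
    maxiter: int = 500,
    compute_se: bool = True,
) -> FitResult:
    """Maximize the selection likelihood by quasi-Newton (L-BFGS-B) with
    central-difference gradients on (beta, gamma, log alpha[, theta])."""
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    if data.n < 20:
        raise ValueError("at least 20 respondents are required for fitting")
    for name, X in (("participation", data.X_part), ("duration", data.X_dur[data.s == 1])):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DesignError(f"{name} design is rank deficient")

    if start is not None:
        x0 = _pack(start)
        if family == "frank" and start.family == "independence":
            theta0 = _theta_start(data, start.participation.beta)
            x0 = np.append(x0, _best_theta_start(data, x0, theta0))
    else:
        beta0 = _probit_start(data)
        gamma0, alpha0 = _gamma_start(data)
        x0 = np.concatenate([beta0, gamma0, [np.log(alpha0)]])
        if family == "frank":
            theta0 = _theta_start(data, beta0)
            x0 = np.append(x0, _best_theta_start(data, x0, theta0))

    # a large finite penalty (not inf) keeps the L-BFGS-B line search able
    # to backtrack out of regions where some contribution underflows
    penalty = 1e10

    def negll(vec: np.ndarray) -> float:
        try:
            return -log_likelihood(_unpack(vec, data, family), data)
        except (LikelihoodError, ValueError, FloatingPointError):
            return penalty

    trace: list[float] = []

    def callback(vec):
        trace.append(-negll(vec))

    k0, k1 = len(data.part_names), len(data.dur_names)
    bounds = [(-_COEF_BOUND, _COEF_BOUND)] * (k0 + k1)
    bounds.append((-_LOG_ALPHA_BOUND, _LOG_ALPHA_BOUND))
    if family == "frank":
        bounds.append((-_THETA_BOUND, _THETA_BOUND))

    res = optimize.minimize(
        negll,
        x0,
        method="L-BFGS-B",
        jac=lambda v: _central_gradient(negll, v),
        bounds=bounds,
        callback=callback,
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
    )
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    if not np.isfinite(res.fun):
        raise ConvergenceError(
            f"optimizer failed: {res.message}", best=res.x, grad_norm=grad_norm
        )
    if not res.success and grad_norm > 1e-2:
        raise ConvergenceError(
            f"optimizer did not converge: {res.message} (grad norm {grad_norm:.3g})",
            best=res.x,
            grad_norm=grad_norm,
        )
    params = _unpack(res.x, data, family)
    loglik = -res.fun
    logger.debug("fit(%s): logL=%.4f after %d iterations", family, loglik, res.nit)

    se, cov, tau_se, hess_pd = {}, np.empty(0), None, True
    tau = kendall_tau(params.dependence) if family == "frank" else None
    if compute_se:
        se, cov, hess_pd, tau_se = standard_errors(params, data, return_cov=True)
    return FitResult(
        params=params,
        loglik=loglik,
        se=se,
        cov=cov,
        converged=bool(res.success),
        n_iter=int(res.nit),
        grad_norm=grad_norm,
        n=data.n,
        n1=data.n1,
        tau=tau,
        tau_se=tau_se,
        hessian_pd=hess_pd,
        loglik_trace=trace,
    )


def standard_errors(params: ModelParams, data: SelectionDataset, return_cov: bool = False):
    """Observed-information standard errors at the optimum.

    The Hessian of the log-likelihood is computed by central differences on
    the estimation scale (log alpha); alpha's standard error is mapped back
    by the delta method, as is the Kendall-tau standard error for the Frank
    family.  A non-positive-definite Hessian triggers a pseudo-inverse
    fallback, flagged through the returned indicator.
    """
    vec = _pack(params)

    def ll(v):
        return log_likelihood(_unpack(v, data, params.family), data)

    H = _central_hessian(ll, vec)
    info = -H
    hess_pd = True
    try:
        cov = np.linalg.inv(info)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
    except np.linalg.LinAlgError:
        hess_pd = False
        logger.warning("observed information not positive definite; using pseudo-inverse")
        cov = np.linalg.pinv(info)

    sd = np.sqrt(np.abs(np.diag(cov)))
    k0, k1 = len(params.participation.names), len(params.duration.names)
    se = {}
    for i, name in enumerate(params.participation.names):
        se[("participation", name)] = float(sd[i])
    for i, name in enumerate(params.duration.names):
        se[("duration", name)] = float(sd[k0 + i])
    # delta method: alpha = exp(log alpha)
    se[("duration", "alpha")] = float(params.duration.alpha * sd[k0 + k1])

    tau_se = None
    if params.family == "frank":
        se_theta = float(sd[k0 + k1 + 1])
        se[("copula", "theta")] = se_theta
        h = 1e-5 * max(1.0, abs(params.dependence.theta))
        dtau = (
            kendall_tau(FrankDependence(params.dependence.theta + h))
            - kendall_tau(FrankDependence(params.dependence.theta - h))
        ) / (2.0 * h)
        tau_se = float(abs(dtau) * se_theta)
        se[("copula", "kendall_tau")] = tau_se

    if return_cov:
        return se, cov, hess_pd, tau_se
    return se


def likelihood_ratio(loglik_restricted: float, loglik_unrestricted: float, df: int = 1):
    """LR statistic ``2 (logL_u - logL_r)`` with its chi-square p-value."""
    stat = 2.0 * (loglik_unrestricted - loglik_restricted)
    pvalue = float(stats.chi2.sf(max(stat, 0.0), df))
    return stat, df, pvalue


def lr_test(restricted: FitResult, unrestricted: FitResult):
    """LR test of the independence model inside the Frank model (df = 1)."""
    if not (restricted.params.family == "independence" and unrestricted.params.family == "frank"):
        raise ValueError("expected an independence fit nested in a frank fit")
    if (restricted.n, restricted.n1) != (unrestricted.n, unrestricted.n1):
        raise ValueError("fits were not computed on the same data")
    stat, df, pvalue = likelihood_ratio(restricted.loglik, unrestricted.loglik)
    if stat < -1e-6:
        raise ValueError(f"negative LR statistic ({stat:.3g}); fits are inconsistent")
    return max(stat, 0.0), df, pvalue
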