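"""Synthetic survey generator and packaged fixtures.

Generates respondent-level datasets with the structure the selection model
assumes: independent covariate blocks (binary / one-hot categorical /
continuous), latent participation and duration utilities joined by a Frank
copula, selection by the observation rules, Gamma durations with
multiplicity-scaled shape, banded multiplicity counts and a three-level
vigour draw.  One root seed drives three independent substreams
(covariates, copula pairs, multiplicity/vigour).

The packaged fixtures carry the published full-sample coefficient tables,
the three worked covariate profiles, the BMI regression coefficients and
the vigour-by-events band counts; they are checksummed at load time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .copulas import FrankDependence, sample_pairs
from .margins import (
    CovariateProfile,
    DURATION_COVARIATES,
    PARTICIPATION_COVARIATES,
    DurationMargin,
    ParticipationMargin,
)
from .prediction import BmiModel
from .selection_model import ModelParams, SelectionDataset

__all__ = [
    "BinaryCovariate",
    "CategoricalCovariate",
    "ContinuousCovariate",
    "GeneratorSpec",
    "SpecError",
    "PackagingError",
    "Fixtures",
    "default_generator_spec",
    "generate_covariates",
    "simulate_selection",
    "generate_dataset",
    "calibrate_participation_intercept",
    "to_episode_records",
    "load_fixtures",
    "DEFAULT_VIGOUR_PROBS",
    "DEFAULT_MULTIPLICITY_BANDS",
]

#: default vigour shares over (low, moderate, high)
DEFAULT_VIGOUR_PROBS = (0.123, 0.254, 0.623)

#: multiplicity bands (inclusive ranges of events per 28 days) with the
#: published participant counts; probabilities are counts / total
DEFAULT_MULTIPLICITY_BANDS = (
    ((1, 4), 1031),
    ((5, 8), 475),
    ((9, 12), 277),
    ((13, 16), 178),
    ((17, 20), 108),
    ((21, 28), 258),
)


class SpecError(ValueError):
    """The generator spec is internally inconsistent."""


class PackagingError(RuntimeError):
    """A packaged fixture failed its checksum."""


@dataclass(frozen=True)
class BinaryCovariate:
    name: str
    prevalence: float

    def __post_init__(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise SpecError(f"{self.name}: prevalence must be in [0, 1]")

    def draw(self, n: int, rng) -> pd.DataFrame:
        return pd.DataFrame({self.name: (rng.uniform(size=n) < self.prevalence).astype(float)})


@dataclass(frozen=True)
class CategoricalCovariate:
    """One-hot dummy group; the implicit reference level takes the
    remaining probability mass."""

    levels: Mapping[str, float]

    def __post_init__(self):
        total = float(sum(self.levels.values()))
        if any(p < 0 for p in self.levels.values()) or total > 1.0 + 1e-12:
            raise SpecError(f"dummy-group probabilities invalid (sum {total:.4f} > 1)")

    def draw(self, n: int, rng) -> pd.DataFrame:
        names = list(self.levels)
        probs = np.array([self.levels[k] for k in names])
        cut = np.concatenate([[0.0], np.cumsum(probs)])
        u = rng.uniform(size=n)
        out = {}
        for i, name in enumerate(names):
            out[name] = ((u >= cut[i]) & (u < cut[i + 1])).astype(float)
        return pd.DataFrame(out)


@dataclass(frozen=True)
class ContinuousCovariate:
    name: str
    mean: float
    sd: float
    lower: Optional[float] = None

    def draw(self, n: int, rng) -> pd.DataFrame:
        x = rng.normal(self.mean, self.sd, size=n)
        if self.lower is not None:
            x = np.maximum(x, self.lower)
        return pd.DataFrame({self.name: x})


CovariateBlock = Union[BinaryCovariate, CategoricalCovariate, ContinuousCovariate]


@dataclass
class GeneratorSpec:
    n: int
    covariates: Sequence[CovariateBlock]
    truth: ModelParams
    seed: int
    multiplicity_bands: Sequence = DEFAULT_MULTIPLICITY_BANDS
    vigour_probs: Sequence[float] = DEFAULT_VIGOUR_PROBS

    def __post_init__(self):
        if self.n < 1:
            raise SpecError("n must be >= 1")
        if self.seed is None:
            raise SpecError("a seed is mandatory")
        if abs(sum(self.vigour_probs) - 1.0) > 1e-9 or len(self.vigour_probs) != 3:
            raise SpecError("vigour_probs must be three probabilities summing to 1")


def generate_covariates(spec: GeneratorSpec, rng=None) -> pd.DataFrame:
    """Draw the covariate table; blocks are mutually independent."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    frames = [block.draw(spec.n, rng) for block in spec.covariates]
    table = pd.concat(frames, axis=1)
    dup = table.columns[table.columns.duplicated()].tolist()
    if dup:
        raise SpecError(f"duplicate covariate names: {dup}")
    return table


def _band_probs(bands) -> tuple[np.ndarray, list]:
    ranges = [b[0] for b in bands]
    weights = np.array([b[1] for b in bands], dtype=float)
    return weights / weights.sum(), ranges


def draw_multiplicity(n: int, rng, bands=DEFAULT_MULTIPLICITY_BANDS) -> np.ndarray:
    """Banded count draw: pick a band, then uniform over its integers."""
    probs, ranges = _band_probs(bands)
    band_idx = rng.choice(len(ranges), size=n, p=probs)
    lo = np.array([r[0] for r in ranges])[band_idx]
    hi = np.array([r[1] for r in ranges])[band_idx]
    return rng.integers(lo, hi + 1)


def draw_vigour(n: int, rng, probs=DEFAULT_VIGOUR_PROBS) -> np.ndarray:
    return rng.choice([1, 2, 3], size=n, p=np.asarray(probs, dtype=float))


def simulate_selection(
    covariates: pd.DataFrame,
    truth: ModelParams,
    q: np.ndarray,
    vigour: np.ndarray,
    seed,
) -> tuple[SelectionDataset, pd.DataFrame]:
    """Apply the observation rules to copula-linked latent utilities.

    Draws ``(u, v)`` from the truth copula; participation is ``u > F(0)``
    with ``F(0) = 1 - Phi(x'beta)``; participant durations are the Gamma
    quantile of ``v`` at shape ``alpha q`` and scale ``exp(x'gamma)`` (the
    duration design includes the drawn vigour dummies).  Returns the fitted
    dataset together with the flat per-respondent table.
    """
    n = len(covariates)
    q = np.asarray(q)
    vigour = np.asarray(vigour)
    if q.shape != (n,) or vigour.shape != (n,):
        raise SpecError("q and vigour draws must match the covariate table length")

    table = covariates.copy()
    table["vigour"] = vigour
    table["vigour_moderate"] = (vigour == 2).astype(float)
    table["vigour_high"] = (vigour == 3).astype(float)

    part_names = list(truth.participation.names)
    dur_names = list(truth.duration.names)
    X0 = _design(table, part_names)
    X1 = _design(table, dur_names)

    uv = sample_pairs(truth.dependence, n, seed)
    xb = X0 @ truth.participation.beta
    F0 = stats.norm.cdf(-xb)
    s = (uv[:, 0] > F0).astype(int)

    lam = np.exp(X1 @ truth.duration.gamma)
    shape = truth.duration.alpha * q
    v = np.clip(uv[:, 1], 1e-15, 1.0 - 1e-15)
    t = np.where(s == 1, special.gammaincinv(shape, v) * lam, np.nan)

    table["s"] = s
    table["t"] = t
    table["q"] = np.where(s == 1, q.astype(float), np.nan)
    dataset = SelectionDataset(
        s=s,
        t=t,
        q=table["q"].to_numpy(),
        X_part=X0,
        X_dur=X1,
        part_names=part_names,
        dur_names=dur_names,
    )
    return dataset, table


def _design(table: pd.DataFrame, names) -> np.ndarray:
    from .margins import design_matrix

    return design_matrix(table, names)


def generate_dataset(spec: GeneratorSpec) -> tuple[SelectionDataset, pd.DataFrame]:
    """Full pipeline: covariates, multiplicity/vigour, copula selection.

    The root seed spawns three independent substreams so that, e.g.,
    enlarging the covariate roster does not perturb the copula draws.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(3)
    rng_cov = np.random.default_rng(streams[0])
    rng_copula = np.random.default_rng(streams[1])
    rng_qv = np.random.default_rng(streams[2])

    covariates = generate_covariates(spec, rng_cov)
    q = draw_multiplicity(spec.n, rng_qv, spec.multiplicity_bands)
    vigour = draw_vigour(spec.n, rng_qv, spec.vigour_probs)
    return simulate_selection(covariates, spec.truth, q, vigour, rng_copula)


def calibrate_participation_intercept(
    spec: GeneratorSpec, target_rate: float, n_probe: int = 20000
) -> ModelParams:
    """Return truth params with the participation constant shifted so the
    mean participation probability over the covariate law hits the target."""
    probe = GeneratorSpec(
        n=n_probe,
        covariates=spec.covariates,
        truth=spec.truth,
        seed=spec.seed,
        multiplicity_bands=spec.multiplicity_bands,
        vigour_probs=spec.vigour_probs,
    )
    cov = generate_covariates(probe)
    names = list(spec.truth.participation.names)
    X0 = _design(cov.assign(vigour_moderate=0.0, vigour_high=0.0), names)
    xb = X0 @ spec.truth.participation.beta

    def gap(delta):
        return stats.norm.cdf(xb + delta).mean() - target_rate

    delta = optimize.brentq(gap, -10.0, 10.0)
    beta = spec.truth.participation.beta.copy()
    beta[names.index("constant")] += delta
    return ModelParams(
        participation=ParticipationMargin(beta, names),
        duration=spec.truth.duration,
        dependence=spec.truth.dependence,
        family=spec.truth.family,
    )


def to_episode_records(table: pd.DataFrame) -> pd.DataFrame:
    """Emit single-sport episode records that re-aggregate to the table.

    Each participant gets one sport with ``d = q`` days and per-day average
    ``t / q`` hours, at an (intensity, effort) pair mapping to the drawn
    vigour; non-participants get a zero-day record so they still appear.
    """
    s_e = {1: (1, 0), 2: (2, 1), 3: (3, 1)}
    rows = []
    for i, row in enumerate(table.itertuples(index=False)):
        rid = f"r{i:06d}"
        if row.s == 1:
            si, ei = s_e[int(row.vigour)]
            rows.append((rid, "sport", int(row.q), row.t / row.q, ei, si))
        else:
            rows.append((rid, "sport", 0, 0.0, 0, 1))
    return pd.DataFrame(
        rows,
        columns=["respondent_id", "sport_id", "d_days", "a_avg_hours", "e_effort", "s_intensity"],
    )


# ---------------------------------------------------------------------------
# packaged fixtures


@dataclass(frozen=True)
class Fixtures:
    n: int
    n1: int
    frank: ModelParams
    independence: ModelParams
    loglik: Mapping[str, float]
    subsample_theta: Mapping[str, float]
    profiles: Mapping[str, CovariateProfile]
    bmi: BmiModel
    vigour_by_events: pd.DataFrame


_FIXTURE_FILES = (
    "estimates_full.json",
    "profiles.json",
    "bmi_coefficients.json",
    "vigour_by_events.json",
)


def _read_fixture(name: str) -> bytes:
    return resources.files("sportsel.fixtures").joinpath(name).read_bytes()


def _verify_checksums() -> None:
    recorded = json.loads(_read_fixture("checksums.json"))
    for name in _FIXTURE_FILES:
        digest = hashlib.sha256(_read_fixture(name)).hexdigest()
        if recorded.get(name) != digest:
            raise PackagingError(f"fixture {name} failed its checksum")


def _model_params(block: dict, family: str) -> ModelParams:
    beta = np.array([block["beta"][n] for n in PARTICIPATION_COVARIATES])
    gamma = np.array([block["gamma"][n] for n in DURATION_COVARIATES])
    return ModelParams(
        participation=ParticipationMargin(beta, list(PARTICIPATION_COVARIATES)),
        duration=DurationMargin(gamma, block["alpha"], list(DURATION_COVARIATES)),
        dependence=FrankDependence(block.get("theta", 0.0)),
        family=family,
    )


def load_fixtures() -> Fixtures:
    """Load and checksum-verify the packaged coefficient/profile fixtures."""
    _verify_checksums()
    est = json.loads(_read_fixture("estimates_full.json"))
    profiles_raw = json.loads(_read_fixture("profiles.json"))
    bmi_raw = json.loads(_read_fixture("bmi_coefficients.json"))
    vig_raw = json.loads(_read_fixture("vigour_by_events.json"))

    vig = pd.DataFrame(
        vig_raw["counts"], index=vig_raw["vigour"], columns=vig_raw["bands"]
    )
    return Fixtures(
        n=est["n"],
        n1=est["n1"],
        frank=_model_params(est["frank"], "frank"),
        independence=_model_params(est["independence"], "independence"),
        loglik={k: est[k]["loglik"] for k in ("frank", "independence")},
        subsample_theta=est["subsample_theta"],
        profiles={k: CovariateProfile(v) for k, v in profiles_raw.items()},
        bmi=BmiModel(bmi_raw),
        vigour_by_events=vig,
    )


def default_generator_spec(n: int = 4380, seed: int = 0) -> GeneratorSpec:
    """A covariate roster shaped like the published descriptive table.

    Block prevalences are overall-sample values obtained by pooling the
    participant and non-participant columns at the published group sizes;
    the truth parameters are the packaged full-sample Frank estimates.
    """
    fx = load_fixtures()
    w1 = fx.n1 / fx.n  # participant share used for pooling
    w0 = 1.0 - w1

    def pool(p1, p0):
        return w1 * p1 + w0 * p0

    covariates: list[CovariateBlock] = [
        BinaryCovariate("gender_male", pool(0.486, 0.433)),
        CategoricalCovariate(
            {
                "age_16_24": pool(0.142, 0.064),
                "age_25_34": pool(0.211, 0.134),
                "age_35_44": pool(0.290, 0.234),
                "age_45_54": pool(0.199, 0.269),
            }
        ),
        ContinuousCovariate("ln_income", pool(10.010, 9.719), 0.82),
        CategoricalCovariate(
            {
                "single": pool(0.242, 0.150),
                "divorced_sep_widowed": pool(0.104, 0.141),
            }
        ),
        ContinuousCovariate("n_children_2_15", pool(0.630, 0.469), 0.90, lower=0.0),
        ContinuousCovariate("n_children_under_2", pool(0.067, 0.070), 0.26, lower=0.0),
        BinaryCovariate("mother_alive", pool(0.727, 0.546)),
        ContinuousCovariate("tv_hours_week", pool(5.822, 7.315), 3.9, lower=0.0),
        BinaryCovariate("car_available", pool(0.847, 0.761)),
        BinaryCovariate("no_education", pool(0.148, 0.386)),
        CategoricalCovariate(
            {
                "retired": pool(0.049, 0.072),
                "unemployed": pool(0.062, 0.047),
                "inactive": pool(0.141, 0.260),
            }
        ),
        CategoricalCovariate(
            {
                "health_very_good": pool(0.449, 0.286),
                "health_good": pool(0.413, 0.395),
                "health_fair": pool(0.113, 0.216),
            }
        ),
        CategoricalCovariate(
            {
                "wellbeing_good": pool(0.643, 0.605),
                "wellbeing_fair": pool(0.212, 0.173),
                "wellbeing_missing": pool(0.026, 0.042),
            }
        ),
        CategoricalCovariate(
            {
                "illness_limiting": pool(0.161, 0.302),
                "illness_non_limiting": pool(0.146, 0.147),
            }
        ),
        BinaryCovariate("accident", pool(0.130, 0.106)),
        ContinuousCovariate("area_sport_hours", pool(1.870, 1.815), 0.25),
        ContinuousCovariate("area_bmi", pool(27.032, 27.095), 0.28),
        CategoricalCovariate(
            {
                "smoker": pool(0.226, 0.355),
                "ex_smoker": pool(0.255, 0.233),
            }
        ),
        CategoricalCovariate(
            {
                "drinker_under_limit": pool(0.454, 0.387),
                "drinker_over_limit": pool(0.242, 0.197),
            }
        ),
        ContinuousCovariate("diet_score", pool(18.450, 17.473), 4.87),
    ]
    return GeneratorSpec(n=n, covariates=covariates, truth=fx.frank, seed=seed)
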