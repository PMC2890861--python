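import numpy as np
import pytest

from sportsel.copulas import FrankDependence
from sportsel.margins import DurationMargin, ParticipationMargin
from sportsel.selection_model import ModelParams, fit
from sportsel.synthetic_data import (
    BinaryCovariate,
    ContinuousCovariate,
    GeneratorSpec,
    generate_dataset,
    load_fixtures,
)

PART_NAMES = ["constant", "x1", "x2"]
DUR_NAMES = ["constant", "x1", "x3", "vigour_moderate", "vigour_high"]


def small_truth(theta: float = 5.0, family: str = "frank") -> ModelParams:
    return ModelParams(
        participation=ParticipationMargin(np.array([0.2, 0.5, -0.4]), PART_NAMES),
        duration=DurationMargin(
            np.array([1.0, 0.3, -0.2, -0.5, -0.4]), 0.25, DUR_NAMES
        ),
        dependence=FrankDependence(theta),
        family=family,
    )


def small_spec(n: int, seed: int, theta: float = 5.0, family: str = "frank") -> GeneratorSpec:
    return GeneratorSpec(
        n=n,
        covariates=[
            BinaryCovariate("x1", 0.5),
            ContinuousCovariate("x2", 0.0, 1.0),
            ContinuousCovariate("x3", 0.0, 1.0),
        ],
        truth=small_truth(theta, family),
        seed=seed,
    )


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def sim5000():
    """One n = 5000 simulated dataset at known Frank truth (theta = 5)."""
    data, table = generate_dataset(small_spec(5000, seed=42))
    return data, table


@pytest.fixture(scope="session")
def fit5000(sim5000):
    """Independence and Frank fits of the shared n = 5000 dataset."""
    data, _ = sim5000
    res_i = fit(data, family="independence")
    res_f = fit(data, family="frank", start=res_i.params)
    return res_i, res_f
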