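import numpy as np
import pytest

from dielgrowth import (
    ExperimentDesign,
    GrowthParameters,
    LightSchedule,
    NoiseModel,
    generate_counts,
)


@pytest.fixture
def schedule():
    return LightSchedule()


@pytest.fixture
def pure_params():
    """Representative pure-culture parameter set."""
    return GrowthParameters(gamma=0.678, delta=0.069, kappa=8.10, n0=9000.0)


@pytest.fixture
def co_params():
    return GrowthParameters(gamma=0.551, delta=0.119, kappa=9.93, n0=12500.0)


@pytest.fixture
def grid():
    """2-h sampling over four diurnal cycles."""
    return np.arange(0.0, 96.1, 2.0)


@pytest.fixture
def noiseless_obs(pure_params):
    return generate_counts(
        pure_params,
        design=ExperimentDesign(),
        noise=NoiseModel(kind="none", cv=0.0),
    )
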