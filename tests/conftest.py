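import numpy as np
import pytest

from rabswitch import (ObjectiveContext, generate_dataset, reference_parameters,
                       simulate)
from rabswitch.model import TimeGrid, default_time_grid


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def default_grid():
    return default_time_grid()


@pytest.fixture(scope="session")
def ref_traj(ref_params):
    """Reference trajectory on the default grid at tight tolerances."""
    return simulate(ref_params)


@pytest.fixture(scope="session")
def small_grid():
    """A short, coarse grid for cheap end-to-end runs."""
    return TimeGrid(0.0, 100.0, 21)


@pytest.fixture(scope="session")
def co_dataset(ref_params):
    """Noise-free complete-observation dataset on the default grid."""
    return generate_dataset(ref_params, "co", 0.0, seed=0)


@pytest.fixture(scope="session")
def co_ctx(co_dataset):
    return ObjectiveContext(co_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
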