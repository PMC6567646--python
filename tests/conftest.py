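import numpy as np
import pytest

from gapnet.likelihood import GapGenePosterior, Observation
from gapnet.model_spec import build_model
from gapnet.solver import SpatialGrid, default_initial
from gapnet.synthetic_data import (
    MaternalInputSpec,
    make_inputs,
    simulate_dataset,
)

# Reduced scale shared by the sampling-heavy tests: a 40-point grid and a
# coarse solver step keep one likelihood evaluation around 5 ms.
SMALL_N = 40
SMALL_DT = 0.02
SMALL_SIGMA = 0.2


@pytest.fixture(scope="session")
def small_grid():
    return SpatialGrid(n_points=SMALL_N)


@pytest.fixture(scope="session")
def default_grid():
    return SpatialGrid(n_points=100)


@pytest.fixture(scope="session")
def small_inputs(small_grid):
    return make_inputs(MaternalInputSpec(), small_grid)


@pytest.fixture(scope="session")
def small_dataset(small_grid):
    return simulate_dataset(
        "B7r", sigma=SMALL_SIGMA, seed=7, grid=small_grid, dt=SMALL_DT
    )


@pytest.fixture(scope="session")
def small_posterior(small_dataset, small_grid):
    ds = small_dataset
    return GapGenePosterior(
        build_model("B7r"),
        Observation(Y=ds.observed, sigma=ds.sigma),
        ds.inputs,
        small_grid,
        dt=SMALL_DT,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
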