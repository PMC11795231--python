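import numpy as np
import pytest

from dentasym import LandmarkScheme, simulate_landmarks
from dentasym.synthetic_data import ShapeSimParams, mean_template


@pytest.fixture(scope="session")
def um1_scheme():
    return LandmarkScheme.for_tooth("UM1")


@pytest.fixture(scope="session")
def lm1_scheme():
    return LandmarkScheme.for_tooth("LM1")


@pytest.fixture(scope="session")
def um1_template(um1_scheme):
    return mean_template(um1_scheme)


@pytest.fixture(scope="session")
def small_um1_set(um1_scheme):
    """10 individuals x 2 sides x 3 replicates of simulated upper molars."""
    params = ShapeSimParams(scheme=um1_scheme, n_individuals=10, seed=2024)
    config_set, truth = simulate_landmarks(params)
    return config_set, truth


@pytest.fixture
def rng():
    return np.random.default_rng(7)
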