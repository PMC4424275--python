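import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sprforest import PopulationParams, generate_population
from sprforest.io import default_params


@pytest.fixture(scope="session")
def shipped_params():
    """The calibrated generator defaults shipped with the package."""
    return default_params()


@pytest.fixture(scope="session")
def small_params():
    """A small, fast population for structural tests."""
    return PopulationParams(n_plots=40, seed=123)


@pytest.fixture(scope="session")
def small_pop(small_params):
    return generate_population(small_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
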