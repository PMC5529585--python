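import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from segscale.observer import make_lattice
from segscale.stimuli import StimulusParams, model_params

#: Coarser lattice used throughout the tests to keep simulations quick;
#: results on the default 0.14-deg lattice are checked in the fast
#: equivalence tests.
TEST_GRID_SPACING = 0.28


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def default_params():
    return StimulusParams()


@pytest.fixture(scope="session")
def two_frame_params():
    return model_params()


@pytest.fixture(scope="session")
def coarse_lattice():
    return make_lattice(7.0, 7.0, TEST_GRID_SPACING)
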