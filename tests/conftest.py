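import numpy as np
import pytest
from hypothesis import settings

from beamsim.config import SetupConfig
from beamsim.rng import RandomStreams

# derandomize: property tests draw the same examples on every run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)


@pytest.fixture
def streams():
    return RandomStreams(20240317)


@pytest.fixture
def small_config():
    """Scaled-down bench configuration for fast pipeline tests."""
    return SetupConfig(
        n00=400,
        K00=5,
        M00=32,
        SRCS=[[2, 0, 0], [0, 2, 0], [0, 0, 3]],
        SEED=11,
    ).validate()
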