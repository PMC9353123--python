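import numpy as np
import pytest

from nutriscape import NutrientSpace, RunConfig


@pytest.fixture
def space():
    """Default rectangular nutrient space."""
    return NutrientSpace()


@pytest.fixture
def square_space():
    return NutrientSpace(0.0, 100.0, 0.0, 100.0)


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
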