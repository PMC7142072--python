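import numpy as np
import pytest

from pelagia import ForcingSeries, ParameterSet


@pytest.fixture
def params() -> ParameterSet:
    """Default parameter set (best laboratory central values)."""
    return ParameterSet()

@pytest.fixture
def starved_forcing() -> ForcingSeries:
    """30 days at 18 degC with no prey (laboratory degrowth)."""
    return ForcingSeries.constant(30, 18.0, 0.0)


@pytest.fixture
def fed_forcing() -> ForcingSeries:
    """120 days at 18 degC at the best-fit laboratory prey level."""
    return ForcingSeries.constant(120, 18.0, 0.9e-5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
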