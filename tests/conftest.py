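import numpy as np
import pytest

from endoclone import ModelParameters


@pytest.fixture
def default_params():
    return ModelParameters()


@pytest.fixture
def neutral_params():
    """Deterministic programmed trajectory: no mutation effects, no
    inheritance noise, hormone level fixed at its mean."""
    return ModelParameters().neutral()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
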