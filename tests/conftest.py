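import numpy as np
import pytest

from cytocin.simulate import NoiseModel


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def no_noise():
    return NoiseModel(p_dropout=0.0, p_split=0.0)
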