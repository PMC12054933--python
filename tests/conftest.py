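import numpy as np
import pytest

from qifnet.params import NetworkParams, default_stdp_params


@pytest.fixture
def params100() -> NetworkParams:
    """Reference network: N=100, 80 E / 10 Hebbian-I / 10 anti-Hebbian-I."""
    return NetworkParams()


@pytest.fixture
def stdp2():
    """Reference STDP parameters at M=2 stored memories (f = 0.1)."""
    return default_stdp_params(M=2)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
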