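import numpy as np
import pytest

from bgloop.topology import build_network


@pytest.fixture(scope="session")
def network():
    """One default healthy network, shared by read-only structural tests."""
    return build_network(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
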