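import numpy as np
import pytest

from r2upp.network import NetworkConfig, build_r2upp


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cfg():
    """Depth-2 network config small enough for fast forward/backward tests."""
    return NetworkConfig(depth=2, base_filters=(4, 8, 16), time_steps=2, deep_supervision=True)


@pytest.fixture(scope="session")
def small_net(small_cfg):
    return build_r2upp(small_cfg, seed=0)


def zero_parameters(module):
    """Set every trainable scalar of a module to zero (helper for identity tests)."""
    for p in module.parameters():
        p.data = np.zeros_like(p.data)
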