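import numpy as np
import pytest

from voxslim.blocks import NetworkConfig, build_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A small but structurally complete network: LMF, ILS, dilation all present."""
    return NetworkConfig(stem_channels=4, stage_widths=(6, 8, 8), lmf_position=1,
                         ils_positions=(1,), dilation_rates=(2,))


@pytest.fixture
def tiny_model(tiny_config):
    return build_network(tiny_config, seed=0)


def numerical_gradient(f, x, eps=1e-3):
    """Central-difference gradient of scalar f() w.r.t. array x (mutated in place)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
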