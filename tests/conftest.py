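import numpy as np
import pytest

from mridenoise import (NetworkConfig, build_fondue, conform,
                        default_head_spec, make_phantom)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fast_phantom():
    """32^3 isotropic phantom, unit scale."""
    return make_phantom(default_head_spec(shape=(32, 32, 32), seed=0))


@pytest.fixture(scope="session")
def fast_conformed(fast_phantom):
    return conform(fast_phantom)


@pytest.fixture(scope="session")
def tiny_net():
    """A 4-filter network for shape/contract tests."""
    return build_fondue(NetworkConfig(n_filt=4, seed=0))


def zero_residual_heads(net) -> None:
    """Zero every output-head convolution so the network is an identity."""
    for name, p in net.named_parameters():
        if "collapse" in name or "conv_out" in name:
            p.data[...] = 0.0
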