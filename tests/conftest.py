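import numpy as np
import pytest

from augmentrl.network import Architecture, HyperParams, Network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_arch():
    """A small hybrid network: 4 sensory, 3 regular, 4 memory, 2 actions."""
    return Architecture.hybrid(4, 3, 4, 2)


@pytest.fixture
def small_net(small_arch, rng):
    return Network(small_arch, hp=HyperParams(), rng=rng)


def make_net(arch, seed=0, **hp_kwargs):
    return Network(arch, hp=HyperParams(**hp_kwargs),
                   rng=np.random.default_rng(seed))
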