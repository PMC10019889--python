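import numpy as np
import pytest

import srnn


@pytest.fixture
def ring20():
    return srnn.ring(20)


@pytest.fixture
def forward_actions():
    return srnn.ring_actions(0.5, 0.25, 0.25)


@pytest.fixture
def uniform_actions():
    return srnn.ring_actions()


@pytest.fixture
def short_forward_walk(ring20, forward_actions):
    return srnn.simulate_walk(ring20, forward_actions, 2000, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
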