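import numpy as np
import pytest

from tmmdesign import LayerStack, default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


def random_alternating_stack(num_layers: int, seed: int, n_hi: float = 2.3, n_lo: float = 1.46) -> LayerStack:
    rng = np.random.default_rng(seed)
    indices = np.where(np.arange(num_layers) % 2 == 0, n_hi, n_lo)
    return LayerStack(1.0, indices, rng.uniform(30.0, 250.0, num_layers), 1.52)


@pytest.fixture
def stack10():
    return random_alternating_stack(10, seed=42)
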