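import numpy as np
import pytest

from nemp.model import ModelConfig, NempModel
from nemp.systems_io import AtomicSystem


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_model():
    """Two-element model, small widths: fast but exercises every code path."""
    cfg = ModelConfig(elements=(1, 8), l_max=2, n_layers=2, n_channels=8,
                      hidden=16, r_c=5.0)
    return NempModel.create(cfg, seed=7)


def random_cluster(rng, n=7, elements=(1, 8), scale=1.5):
    """Random cluster with a minimum-separation guard."""
    while True:
        pos = rng.normal(scale=scale, size=(n, 3))
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > 0.7:
            return AtomicSystem(rng.choice(elements, size=n), pos)


@pytest.fixture
def cluster(rng):
    return random_cluster(rng)
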