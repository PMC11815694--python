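import numpy as np
import pytest

import sctuq as sq
from sctuq.translation import TrainConfig, train


@pytest.fixture(scope="session")
def phantom_pair():
    """One default-condition phantom pair (64x64x32)."""
    return sq.generate_phantom_pair(sq.PhantomConfig())


@pytest.fixture(scope="session")
def small_cohort():
    """Two small phantoms for fast training smoke tests."""
    cfg = sq.PhantomConfig(shape=(32, 32, 16))
    return sq.generate_cohort(2, base_config=cfg, seed=3)


@pytest.fixture(scope="session")
def tiny_model(small_cohort):
    """A 2-epoch, width-8 translator: cheap but structurally complete."""
    cfg = TrainConfig(epochs=2, width=8, seed=5, loss_region="all")
    return train(small_cohort, cfg)


def rand_volume(shape=(8, 8, 8), seed=0, semantics="Gy", low=0.0, high=1.0):
    rng = np.random.default_rng(seed)
    return sq.Volume(rng.uniform(low, high, shape), (2.0, 2.0, 2.0), semantics=semantics)
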