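import numpy as np
import pytest

from aposim.config import ExperimentConfig
from aposim.world import World
from aposim import instructions as ins


@pytest.fixture
def tiny_cfg():
    """Small arena with the floor disabled: attacks always permitted."""
    return ExperimentConfig(width=12, height=12, class_cap=1000, prey_floor=0,
                            n_updates=0, n_replicates=1)


@pytest.fixture
def tiny_world(tiny_cfg):
    return World(tiny_cfg, seed=1234)


@pytest.fixture
def idle_genome():
    """Single no-op; the organism does nothing when executed."""
    return np.array([ins.NOP_A], dtype=np.int8)


def grid_search_logit_mle(levels, y, rounds=6, size=41):
    """Brute-force likelihood grid search: an independent oracle for the
    avoidance-model MLE (coarse-to-fine refinement to < 1e-3)."""
    b0, h0 = 0.0, 12.0
    b1, h1 = 0.0, 60.0
    for _ in range(rounds):
        g0 = np.linspace(b0 - h0, b0 + h0, size)
        g1 = np.linspace(b1 - h1, b1 + h1, size)
        B0, B1 = np.meshgrid(g0, g1, indexing="ij")
        eta = B0[..., None] + B1[..., None] * levels[None, None, :]
        ll = np.where(y[None, None, :] == 1,
                      -np.logaddexp(0, -eta), -np.logaddexp(0, eta)).sum(axis=-1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        b0, b1 = g0[i], g1[j]
        h0 = 2 * (g0[1] - g0[0])
        h1 = 2 * (g1[1] - g1[0])
    return b0, b1
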