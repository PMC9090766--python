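import numpy as np
import pytest

from marginalflock import (Adjacency, BoxGeometry, ModelParams, NeighbourRule,
                           ParticleState, init_lattice)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_box():
    return BoxGeometry.cubic(6.0)


@pytest.fixture
def lattice_state(small_box):
    return init_lattice(small_box, spacing=1.0, v0=1.0, direction=(0, 0, 1))


@pytest.fixture
def metric_rule():
    return NeighbourRule(kind="metric", r_c=1.2, n_c=6)


def random_state(rng, n=5, box_side=10.0, v0=1.0):
    """Random positions in a box and velocities with speeds near v0."""
    pos = rng.uniform(0, box_side, size=(n, 3))
    vel = rng.normal(scale=0.4, size=(n, 3))
    vel += v0 * np.array([0.0, 0.0, 1.0])
    return ParticleState(0.0, pos, vel)


def random_adjacency(rng, n):
    """Random symmetric adjacency without self-edges."""
    m = rng.random((n, n)) < 0.5
    m = np.triu(m, 1)
    m = m | m.T
    return Adjacency(m)
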