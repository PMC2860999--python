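"""Shared fixtures: tiny mazes, grids and hand-checkable transition models."""

import numpy as np
import pytest
from scipy import sparse

from sensopt.env_sim import Maze, MotorParams, make_maze
from sensopt.microstates import TransitionModel, build_grid


@pytest.fixture(scope="session")
def square_maze():
    return make_maze("square", 20.0)


@pytest.fixture(scope="session")
def circle_maze():
    return make_maze("circular", 20.0)


@pytest.fixture(scope="session")
def irregular_maze():
    return make_maze("irregular", 20.0)


@pytest.fixture(scope="session")
def small_square():
    """A 6x6 arena for fast exploration tests."""
    return make_maze("square", 6.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def corridor_model(n: int = 5, K: int = 2) -> TransitionModel:
    """Deterministic 1 x n corridor: action 0 moves east, action 1 west.

    At the walls the agent stays put (reflection bounces it back into
    the same cell).
    """
    mats = []
    for k in range(K):
        rows, cols = [], []
        for i in range(n):
            j = min(i + 1, n - 1) if k == 0 else max(i - 1, 0)
            rows.append(i)
            cols.append(j)
        mats.append(
            sparse.csr_matrix((np.ones(n), (rows, cols)), shape=(n, n))
        )
    visits = np.full((n, K), 10, dtype=np.int64)
    return TransitionModel(tm=mats, visit_counts=visits)


def random_model(M: int, K: int, rng: np.random.Generator, density: float = 0.3) -> TransitionModel:
    """Random row-stochastic transition model for property tests."""
    mats = []
    for _ in range(K):
        dense = rng.random((M, M)) * (rng.random((M, M)) < density)
        # guarantee at least one nonzero per row
        dense[np.arange(M), rng.integers(0, M, M)] += 0.5
        dense /= dense.sum(axis=1, keepdims=True)
        mats.append(sparse.csr_matrix(dense))
    visits = np.full((M, K), 7, dtype=np.int64)
    return TransitionModel(tm=mats, visit_counts=visits)


@pytest.fixture
def corridor5():
    return corridor_model(5)


@pytest.fixture
def random_model_factory():
    return random_model
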