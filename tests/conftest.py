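import numpy as np
import pytest

from crossfeed.model import ColonyState, ModelParams, SPECIES_1, SPECIES_2


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def empty_state():
    return ColonyState.empty(21)


@pytest.fixture
def default_params():
    return ModelParams(lattice_size=21)


class ScriptedRNG:
    """Deterministic stand-in for numpy Generator used in executor tests.

    ``uniforms`` feeds .random() calls, ``ints`` feeds .integers() calls;
    each falls back to a seeded generator when its queue is exhausted.
    """

    def __init__(self, uniforms=(), ints=()):
        self.uniforms = list(uniforms)
        self.ints = list(ints)
        self._fallback = np.random.default_rng(0)

    def random(self):
        if self.uniforms:
            return self.uniforms.pop(0)
        return self._fallback.random()

    def integers(self, *args):
        if self.ints:
            return self.ints.pop(0)
        return self._fallback.integers(*args)


@pytest.fixture
def scripted_rng():
    return ScriptedRNG


def half_plane_state(n=41):
    """Species 1 on the left half, species 2 on the right."""
    grid = np.zeros((n, n), dtype=np.int8)
    grid[:, : n // 2] = SPECIES_1
    grid[:, n // 2:] = SPECIES_2
    return ColonyState(grid, np.zeros((n, n)), np.zeros((n, n)))


def quadrant_state(n=41):
    """Four alternating species quadrants around the centre."""
    grid = np.zeros((n, n), dtype=np.int8)
    c = n // 2
    xs, ys = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    q1 = (xs >= c) & (ys >= c)
    q3 = (xs < c) & (ys < c)
    grid[q1 | q3] = SPECIES_1
    grid[~(q1 | q3)] = SPECIES_2
    return ColonyState(grid, np.zeros((n, n)), np.zeros((n, n)))
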