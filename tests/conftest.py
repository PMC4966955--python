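import numpy as np
import pytest

from eoflux import SpaceTimeField, SyntheticConfig, generate_truth


@pytest.fixture
def rng():
    return np.random.default_rng(20250924)


@pytest.fixture
def small_field(rng):
    """A gap-free 4x5 grid x 12 steps random field."""
    values = rng.normal(50.0, 10.0, size=(20, 12))
    return SpaceTimeField(
        values=values,
        mask=np.zeros((20, 12), dtype=bool),
        grid_shape=(4, 5),
        times=np.arange(12, dtype=float),
    )


@pytest.fixture
def rank3_truth():
    """Default synthetic truth: 40x40 grid, 46 8-day steps, exact rank 3."""
    return generate_truth(SyntheticConfig(seed=7))


def make_low_rank(P, N, rank, rng, mean=50.0):
    """Exact rank-`rank` matrix plus a constant mean, as a SpaceTimeField.

    Grid is (P, 1) so the matrix is exactly the pixel-by-time layout.
    """
    u = rng.normal(size=(P, rank))
    v = rng.normal(size=(N, rank))
    values = mean + u @ v.T
    return SpaceTimeField(
        values=values,
        mask=np.zeros((P, N), dtype=bool),
        grid_shape=(P, 1),
        times=np.arange(N, dtype=float),
    )
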