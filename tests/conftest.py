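import numpy as np
import pytest

from bznmf.model import Factorization, SignalMatrix, TimeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_instance(rng):
    """Random 8x5 signal with a random rank-3 factorization (shapes match)."""
    grid = TimeGrid(np.sort(rng.uniform(0.1, 50.0, 8)))
    I = SignalMatrix(rng.uniform(0.0, 1.0, (8, 5)), grid)
    f = Factorization(
        np.sort(rng.uniform(0.5, 60.0, 3)), rng.uniform(0.05, 1.0, (3, 5)), grid
    )
    return I, f


def random_instance(rng, m=8, n=5, r=3, t_hi=50.0):
    grid = TimeGrid(np.sort(rng.uniform(0.1, t_hi, m)))
    I = SignalMatrix(rng.uniform(0.0, 1.0, (m, n)), grid)
    f = Factorization(
        np.sort(rng.uniform(0.5, 60.0, r)), rng.uniform(0.05, 1.0, (r, n)), grid
    )
    return I, f


def exact_instance(rng, m=8, n=5, r=2):
    """Signal constructed exactly as W @ H for a known factorization."""
    grid = TimeGrid(np.sort(rng.uniform(0.1, 50.0, m)))
    f = Factorization(
        np.sort(rng.uniform(1.0, 40.0, r)), rng.uniform(0.05, 1.0, (r, n)), grid
    )
    from bznmf.model import reconstruct

    return SignalMatrix(reconstruct(f), grid), f
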