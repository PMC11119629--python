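import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from rpcross import (
    EmbeddingParams,
    embed,
    pairwise_distances,
    recurrence_matrix,
)
from rpcross.synthetic import toy_vector

TOY_PARAMS = EmbeddingParams(tau=2, dim=1)


@pytest.fixture
def toy():
    return toy_vector()


@pytest.fixture
def toy_dist(toy):
    return pairwise_distances(embed(toy, TOY_PARAMS))


@pytest.fixture
def toy_m01(toy_dist):
    """The worked-example matrix at lambda = 0.1."""
    return recurrence_matrix(toy_dist, 0.1)


@pytest.fixture
def toy_m09(toy_dist):
    """The worked-example matrix at lambda = 0.9 (all recurrent)."""
    return recurrence_matrix(toy_dist, 0.9)


def random_recurrence(rng, side_max=60):
    """A random symmetric binary matrix with zero diagonal, as the package type."""
    from rpcross.recurrence import RecurrenceMatrix

    n = int(rng.integers(3, side_max + 1))
    upper = rng.random((n, n)) < rng.uniform(0.05, 0.95)
    entries = np.triu(upper, 1).astype(np.uint8)
    entries = entries + entries.T
    rate = float(np.count_nonzero(entries == 0)) / (n * n)
    return RecurrenceMatrix(entries=entries, lam=0.0, recurrence_rate=rate,
                            norm_name="euclidean")
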