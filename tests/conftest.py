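import numpy as np
import pytest

from dbgcnmda import AssociationMatrix, SimilarityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def tiny_assoc():
    """2x2 identity-pattern association network used in hand-computed examples."""
    return AssociationMatrix(["m1", "m2"], ["d1", "d2"], np.eye(2))


def random_assoc(rng, m, n, n_pos):
    """Association matrix with exactly n_pos positive cells."""
    values = np.zeros(m * n)
    values[rng.choice(m * n, size=n_pos, replace=False)] = 1.0
    return AssociationMatrix(
        [f"m{i}" for i in range(m)],
        [f"d{j}" for j in range(n)],
        values.reshape(m, n),
    )


def random_similarity(rng, n, kind="functional"):
    raw = rng.random((n, n))
    values = (raw + raw.T) / 2
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix([f"e{i}" for i in range(n)], values, kind=kind)
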