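import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_group_problem(rng):
    """Cell-means design for groups of 4 and 4, difference contrast, noise."""
    labels = np.repeat([0, 1], [4, 4])
    M = np.zeros((8, 2))
    M[np.arange(8), labels] = 1.0
    C = np.array([[1.0], [-1.0]])
    Y = rng.standard_normal(8)
    return Y, M, C, labels


@pytest.fixture
def regression_problem(rng):
    """Random full-rank regression design with nuisance and intercept."""
    N = 14
    M = np.column_stack(
        [rng.standard_normal(N), rng.standard_normal(N), np.ones(N)]
    )
    C = np.array([[1.0], [0.0], [0.0]])
    Y = rng.standard_normal((N, 3))
    return Y, M, C
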