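import numpy as np
import pandas as pd
import pytest

from thermoclass import simulate
from thermoclass.expression import ExpressionMatrix, sample_name


@pytest.fixture(scope="session")
def small_truth():
    return simulate.default_truth(seed=7, n_genes=800)


@pytest.fixture(scope="session")
def small_counts(small_truth):
    return simulate.simulate_counts(small_truth)


@pytest.fixture(scope="session")
def small_tpm(small_counts):
    from thermoclass.quant import tpm_no_length

    return tpm_no_length(small_counts)


@pytest.fixture(scope="session")
def growth_data():
    return simulate.simulate_growth(seed=7)


def two_group_matrix(y: np.ndarray) -> ExpressionMatrix:
    """Wrap a genes x 4 array as a 2-vs-2 matrix (A_25_r1..A_25_r2, B_25_r1..)."""
    cols = [
        sample_name("A", 25, 1),
        sample_name("A", 25, 2),
        sample_name("B", 25, 1),
        sample_name("B", 25, 2),
    ]
    values = pd.DataFrame(
        np.asarray(y), index=[f"g{i}" for i in range(len(y))], columns=cols
    )
    return ExpressionMatrix(values)


def nb_draw(rng, mu, phi, n):
    """Gamma-Poisson NB draws: genes x n columns."""
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    cols = []
    for _ in range(n):
        lam = rng.gamma(1.0 / phi, mu * phi)
        cols.append(rng.poisson(lam))
    return np.column_stack(cols)
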