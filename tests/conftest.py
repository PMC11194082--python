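import numpy as np
import pytest
import scipy.sparse as sp

from sctc import ExpressionMatrix, TrajectoryConfig, filter_empty, generate_trajectory
from sctc.synthetic import toy_bipartite_fixture


def random_matrix(seed, n_cells=10, n_genes=12, density=0.5):
    """Random non-negative fixture with no empty rows/columns."""
    rng = np.random.default_rng(seed)
    while True:
        X = rng.random((n_cells, n_genes)) * (rng.random((n_cells, n_genes)) < density)
        if (X.sum(axis=1) > 0).all() and (X.sum(axis=0) > 0).all():
            return ExpressionMatrix(sp.csr_matrix(X))


@pytest.fixture
def toy():
    return toy_bipartite_fixture()


@pytest.fixture
def rand10x12():
    return random_matrix(42)


def _tiers_of(m):
    # gene ids encode their tier as "t<tier>_g<idx>"
    return np.array([int(str(g).split("_")[0][1:]) for g in m.gene_ids])


@pytest.fixture(scope="session")
def dip_trajectory():
    m, _, _ = generate_trajectory(TrajectoryConfig(seed=1))
    m = filter_empty(m)
    return m, m.stage_labels, _tiers_of(m)


@pytest.fixture(scope="session")
def monotone_trajectory():
    m, _, _ = generate_trajectory(
        TrajectoryConfig(diversity_profile="monotone", seed=1)
    )
    m = filter_empty(m)
    return m, m.stage_labels, _tiers_of(m)
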