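import numpy as np
import pytest

from grnwalker.config import RunConfig
from grnwalker.gcen import ExpressionMatrix, build_gcen
from grnwalker.synthetic import SyntheticGRNSpec, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_expr(rng):
    """10 genes x 8 cells, first 3 genes flagged as TFs."""
    values = rng.gamma(2.0, 2.0, size=(10, 8))
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"G{i}" for i in range(10)],
        cell_ids=[f"C{i}" for i in range(8)],
        is_tf=np.array([True] * 3 + [False] * 7),
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic dataset shared across tests (cheap to fit)."""
    return simulate_dataset(
        SyntheticGRNSpec(n_genes=40, n_tfs=6, n_cells=50, edges_per_tf=5.0, seed=7)
    )


@pytest.fixture(scope="session")
def tiny_gcen(tiny_dataset):
    return build_gcen(tiny_dataset.expr, 0.1)


@pytest.fixture
def tiny_config():
    return RunConfig(seed=11, epochs=3, subgraph_size=20, bootstrap_iterations=10)
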