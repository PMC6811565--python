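import networkx as nx
import numpy as np
import pytest

from coexpharm.types import ExpressionDataset, Interactome


@pytest.fixture
def small_dataset() -> ExpressionDataset:
    """8 genes x 12 samples, 6 healthy / 6 diseased, reproducible."""
    rng = np.random.default_rng(42)
    return ExpressionDataset(
        tissue_name="toy",
        gene_ids=[f"g{i}" for i in range(8)],
        sample_ids=[f"s{i}" for i in range(12)],
        values=rng.normal(size=(8, 12)),
        phenotype=np.array([0] * 6 + [1] * 6),
    )


@pytest.fixture
def path_interactome() -> Interactome:
    """Path graph n0 - n1 - ... - n5."""
    g = nx.path_graph(6)
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(6)})
    return Interactome(graph=g, restricted_to_lcc=True)


def make_dataset(values, phenotype=None, tissue="toy"):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionDataset(
        tissue_name=tissue,
        gene_ids=[f"g{i}" for i in range(n)],
        sample_ids=[f"s{i}" for i in range(m)],
        values=values,
        phenotype=np.array(phenotype if phenotype is not None else [0] * (m // 2) + [1] * (m - m // 2)),
    )
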