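import networkx as nx
import numpy as np
import pandas as pd
import pytest

from polypnet import simulate
from polypnet.containers import ExpressionMatrix, SampleMetadata


def make_expression(values: np.ndarray, phenotypes, batches=None,
                    genes=None) -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix with generated ids."""
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{i:03d}" for i in range(n_samples)]
    batches = batches or ["b1"] * n_samples
    meta = SampleMetadata(pd.DataFrame(
        {"phenotype": list(phenotypes), "batch": list(batches)},
        index=pd.Index(samples, name="sample_id")))
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), meta)


def weighted(graph: nx.Graph, w: float = 1.0) -> nx.Graph:
    for u, v in graph.edges:
        graph.edges[u, v].setdefault("weight", w)
    return graph


@pytest.fixture
def two_triangles() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                      ("x", "y"), ("y", "z"), ("x", "z")])
    return weighted(g)


@pytest.fixture(scope="session")
def small_cfg() -> simulate.SimConfig:
    """A scaled-down cohort with the reference structure: two
    phenotype-linked 40-gene modules in a 400-gene, two-batch cohort."""
    return simulate.reference_config(seed=11, n_genes=400, module_size=40,
                                     n_de=10, n_samples_per_batch=(30, 30))


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    """(probe_matrix, metadata, truth) for the scaled-down cohort."""
    return simulate.simulate_cohort(small_cfg)
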