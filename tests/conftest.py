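import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netphix import AlterationMatrix, PhenotypeProfile


def random_instance(seed: int, n_genes: int = 8, n_samples: int = 12, edge_p: float = 0.35,
                    alt_p: float = 0.4):
    """Small random instance: dense-ish graph, Bernoulli alterations, normal weights."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    G = nx.gnp_random_graph(n_genes, edge_p, seed=int(rng.integers(2**31)))
    G = nx.relabel_nodes(G, dict(enumerate(genes)))
    for _, _, d in G.edges(data=True):
        d["score"] = 1.0
    A = AlterationMatrix(pd.DataFrame(
        (rng.random((n_genes, n_samples)) < alt_p).astype(np.int8),
        index=genes, columns=samples))
    w = PhenotypeProfile(pd.Series(rng.normal(0, 1, n_samples), index=samples))
    return A, w, G


@pytest.fixture
def worked_instance():
    """The 2-gene / 4-sample instance with weights [3, 2, -1, 1]."""
    A = AlterationMatrix(pd.DataFrame(
        [[1, 0, 1, 0], [1, 0, 0, 1]],
        index=["g1", "g2"], columns=["p1", "p2", "p3", "p4"], dtype="int8"))
    w = PhenotypeProfile(pd.Series([3.0, 2.0, -1.0, 1.0],
                                   index=["p1", "p2", "p3", "p4"]))
    return A, w


@pytest.fixture
def path_network():
    """Path a - b - c with unit scores."""
    G = nx.Graph()
    G.add_edge("a", "b", score=1.0)
    G.add_edge("b", "c", score=1.0)
    return G
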