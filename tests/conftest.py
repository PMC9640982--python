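import networkx as nx
import numpy as np
import pandas as pd
import pytest

from denet.de_sets import DESetCollection
from denet.expression import CountMatrix, StudyDesign
from denet.pathways import BioNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_counts():
    """3 genes x 4 samples, all-positive so size factors are defined."""
    counts = np.array([[10, 20, 30, 40], [100, 110, 90, 120], [5, 8, 6, 9]])
    return CountMatrix(("g1", "g2", "g3"), ("s1", "s2", "s3", "s4"), counts)


@pytest.fixture
def tiny_design():
    rows = [
        ("D0_0nM", "D0", 0),
        ("D4_0nM", "D4", 0), ("D4_10nM", "D4", 10), ("D4_100nM", "D4", 100),
        ("D9_0nM", "D9", 0), ("D9_10nM", "D9", 10), ("D9_100nM", "D9", 100),
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "timepoint", "dose_nM"])
    return StudyDesign(df)


def make_network(graph: nx.Graph) -> BioNetwork:
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(graph.edges, pathways={"fixture"})
    return BioNetwork(g)


@pytest.fixture
def path_network():
    """A - B - C - D path."""
    return make_network(nx.path_graph(["A", "B", "C", "D"]))


@pytest.fixture(scope="session")
def ba_network():
    """BA(300, 3) network shared across topology tests."""
    g = nx.barabasi_albert_graph(300, 3, seed=42)
    return make_network(nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes}))


def make_collection(sets, timepoints=("D0", "D4", "D9", "D12", "D18", "D28")):
    """sets: {(tp, dose): iterable of genes or {gene: sign}}."""
    norm = {}
    for cond, genes in sets.items():
        norm[cond] = genes if isinstance(genes, dict) else {g: 1 for g in genes}
    return DESetCollection(norm, tuple(timepoints))
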