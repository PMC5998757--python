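import networkx as nx
import pytest

from litlink import GeneDictionary


@pytest.fixture
def t2d_dictionary() -> GeneDictionary:
    """Small hand-made dictionary with overlapping and multi-word synonyms."""
    d = GeneDictionary()
    d.add("INSR", ["INSR", "insulin receptor"], "gene")
    d.add("IRS1/IRS", ["IRS1", "IRS"], "gene")
    d.add("INS", ["INS", "insulin"], "gene")
    d.add("TNFA", ["TNF-alpha", "TNFA"], "gene")
    d.add("GLP-1", ["GLP-1"], "gene")
    d.add("T2DM", ["type 2 diabetes"], "disease")
    return d


@pytest.fixture
def triangle_with_tail() -> nx.Graph:
    """Triangle A-B-C plus tail C-D; distances 0/1/2 from any prev node."""
    g = nx.Graph()
    g.add_edge("A", "B", weight=2)
    g.add_edge("B", "C", weight=1)
    g.add_edge("A", "C", weight=3)
    g.add_edge("C", "D", weight=1)
    return g


@pytest.fixture
def weighted_k4() -> nx.Graph:
    g = nx.complete_graph(4)
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    for i, (u, v) in enumerate(sorted(g.edges)):
        g[u][v]["weight"] = i + 1
    return g
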