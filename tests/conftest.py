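import networkx as nx
import pytest

from netsuit import PPINetwork
from netsuit.synth import make_graph


@pytest.fixture
def star5() -> PPINetwork:
    """Hub G000 with four leaves."""
    return make_graph("star", 5)


@pytest.fixture
def path5() -> PPINetwork:
    return make_graph("path", 5)


@pytest.fixture
def two_components() -> PPINetwork:
    """A 4-path plus a disjoint edge (disconnected fixture)."""
    g = nx.path_graph(4)
    g = nx.relabel_nodes(g, {i: f"A{i}" for i in range(4)})
    g.add_edge("B0", "B1")
    nx.set_edge_attributes(g, 1.0, "confidence")
    return PPINetwork(g, name="two_components")


def labelled(net: PPINetwork, damaged: set[str]) -> PPINetwork:
    net.set_labels({v: ("damaged" if v in damaged else "intact") for v in net.g})
    return net
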