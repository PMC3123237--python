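import random

import networkx as nx
import pytest


def random_graph(rng: random.Random, n_nodes: int, p: float) -> nx.Graph:
    """Erdos-Renyi graph with string node labels and a deterministic stream."""
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j])
    return g


@pytest.fixture
def triangle() -> nx.Graph:
    return nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def star() -> nx.Graph:
    return nx.Graph([("h", "l1"), ("h", "l2"), ("h", "l3")])


@pytest.fixture
def path3() -> nx.Graph:
    return nx.Graph([("a", "b"), ("b", "c")])


@pytest.fixture
def bridged_k4s() -> nx.Graph:
    """Two K4 cliques a1..a4 and b1..b4 joined by the single bridge a1-b1."""
    g = nx.Graph()
    for group in (["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(group[i], group[j])
    g.add_edge("a1", "b1")
    return g


@pytest.fixture
def k4() -> nx.Graph:
    return nx.complete_graph(["a", "b", "c", "d"])
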