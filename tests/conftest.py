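"""Shared fixtures: tiny graphs with known structure."""

from __future__ import annotations

import networkx as nx
import pytest

from woundnet.network import WeightedNetwork


def make_network(edges, seeds=(), nodes=()):
    """Build a WeightedNetwork from (u, v, weight) triples."""
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for u, v, w in edges:
        graph.add_edge(u, v, weight=w)
    return WeightedNetwork(graph=graph, seeds=frozenset(seeds))


@pytest.fixture
def path_abc():
    """Unweighted path A - B - C."""
    return make_network([("A", "B", 1.0), ("B", "C", 1.0)])


@pytest.fixture
def star_center_4():
    """Star with center S and 4 leaves."""
    return make_network([("S", f"L{i}", 1.0) for i in range(4)])


@pytest.fixture
def two_cliques():
    """Two unit-weight K5 cliques joined by a single weight-0.1 edge."""
    edges = []
    left = [f"A{i}" for i in range(5)]
    right = [f"B{i}" for i in range(5)]
    for group in (left, right):
        for i in range(5):
            for j in range(i + 1, 5):
                edges.append((group[i], group[j], 1.0))
    edges.append((left[0], right[0], 0.1))
    return make_network(edges), frozenset(left), frozenset(right)
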