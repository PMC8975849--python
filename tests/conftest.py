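"""Shared fixtures and independent brute-force oracles.

The oracles implement the defining construction directly — exhaustive subset
checks for maximal cliques, explicit k-clique enumeration plus adjacency BFS
for communities — and stay independent of the union-find/maximal-clique path
used by the package.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pytest


# ---------------------------------------------------------------------------
# brute-force oracles


def oracle_maximal_cliques(graph: nx.Graph) -> set[frozenset]:
    """All maximal cliques by testing every node subset (graphs <= ~12 nodes)."""
    nodes = list(graph.nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for subset in combinations(nodes, r):
            if all(graph.has_edge(a, b) for a, b in combinations(subset, 2)):
                cliques.append(frozenset(subset))
    return {
        c for c in cliques
        if not any(c < other for other in cliques)
    }


def oracle_k_cliques(graph: nx.Graph, k: int) -> list[frozenset]:
    """Every k-clique, by exhaustive combination testing."""
    return [
        frozenset(subset)
        for subset in combinations(sorted(graph.nodes, key=str), k)
        if all(graph.has_edge(a, b) for a, b in combinations(subset, 2))
    ]


def oracle_k_clique_communities(graph: nx.Graph, k: int) -> set[frozenset]:
    """Communities straight from the definition: components of k-clique adjacency.

    Builds the graph whose vertices are the k-cliques, links pairs sharing
    k-1 nodes, and returns the node union of each connected component.
    """
    kcliques = oracle_k_cliques(graph, k)
    meta = nx.Graph()
    meta.add_nodes_from(range(len(kcliques)))
    for i, j in combinations(range(len(kcliques)), 2):
        if len(kcliques[i] & kcliques[j]) == k - 1:
            meta.add_edge(i, j)
    out = set()
    for component in nx.connected_components(meta):
        nodes: set = set()
        for idx in component:
            nodes |= kcliques[idx]
        out.add(frozenset(nodes))
    return out


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    return nx.fast_gnp_random_graph(n, p, seed=seed)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def triangle() -> nx.Graph:
    return nx.complete_graph(3)


@pytest.fixture
def two_triangles_shared_node() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (2, 4)])
    return g


@pytest.fixture
def weighted_fixture() -> nx.Graph:
    """Six weighted edges spanning weak and strong links."""
    g = nx.Graph()
    for u, v, w in [
        ("a", "b", 0.05), ("b", "c", 0.10), ("c", "d", 0.20),
        ("d", "e", 0.50), ("e", "f", 0.01), ("a", "c", 0.30),
    ]:
        g.add_edge(u, v, weight=w)
    return g


@pytest.fixture(scope="session")
def grown_2000() -> nx.Graph:
    """One grown network at study-condition defaults, shared across tests."""
    from cliqueperc import GrowthParams, grow_network

    return grow_network(GrowthParams(n_target=2000, seed=42))
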