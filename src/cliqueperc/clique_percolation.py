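"""k-clique percolation: communities, percolation profiles, critical clique size.

A *k-clique* is a complete subgraph on k nodes.  Two k-cliques are *adjacent*
when they share k-1 nodes, and a *k-clique percolation cluster* (community) is
the node union of a maximal set of k-cliques connected through chains of
adjacent k-cliques.  The fraction of nodes in the largest such cluster,
f_cc(k), summarizes how far cliques of a given order can percolate; the
largest k for which f_cc(k) is non-negligible is the critical clique size k_c.

For Erdos-Renyi graphs the percolation threshold is analytic:
``p_c(k) = 1 / [N (k-1)]^(1/(k-1))``, reducing to the familiar giant-component
threshold 1/N at k=2.

Communities are computed from the maximal cliques (Bron-Kerbosch with
pivoting, via networkx): two maximal cliques of size >= k lie in the same
community iff they are connected through pairwise overlaps of >= k-1 nodes.
This is equivalent to taking connected components of the direct k-clique
adjacency relation — every k-clique sits inside some maximal clique, any two
k-cliques within one clique are chain-connected, and an overlap of k-1 nodes
between maximal cliques provides the bridging k-cliques — and is validated
against a brute-force implementation of the definition in the test suite.

Edge weights are ignored throughout: percolation here is purely topological.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import json

import networkx as nx

__all__ = [
    "CliqueLimitExceeded",
    "KCliqueCommunitySet",
    "PercolationProfile",
    "enumerate_maximal_cliques",
    "k_clique_communities",
    "percolation_profile",
    "critical_k",
    "pc_threshold",
    "write_communities",
    "write_profile",
]

#: Abort threshold for pathological inputs whose maximal-clique count explodes.
DEFAULT_MAX_CLIQUES = 10_000_000


class CliqueLimitExceeded(RuntimeError):
    """Raised when maximal-clique enumeration exceeds the configured guard limit."""


@dataclass(frozen=True)
class KCliqueCommunitySet:
    """The k-clique communities of a graph for one value of k.

    Each community is the node union of one connected component of the
    k-clique adjacency relation; communities are sorted largest first and a
    node may belong to several of them.
    """

    k: int
    communities: tuple[frozenset, ...]

    def __len__(self) -> int:
        return len(self.communities)

    @property
    def largest_size(self) -> int:
        return len(self.communities[0]) if self.communities else 0

    def node_union(self) -> frozenset:
        out: set = set()
        for c in self.communities:
            out |= c
        return frozenset(out)


@dataclass(frozen=True)
class PercolationProfile:
    """f_cc(k) for k = 2..k_max on a fixed graph.

    ``entries`` maps k to the fraction of nodes in the largest k-clique
    community; ``union_fractions`` is the secondary statistic covering all
    communities; ``largest_sizes`` and ``n_communities`` carry the raw counts.
    """

    entries: dict[int, float]
    n_nodes: int
    union_fractions: dict[int, float] = field(default_factory=dict)
    largest_sizes: dict[int, int] = field(default_factory=dict)
    n_communities: dict[int, int] = field(default_factory=dict)

    def f_cc(self, k: int) -> float:
        return self.entries[k]

    @property
    def k_values(self) -> list[int]:
        return sorted(self.entries)


def enumerate_maximal_cliques(
    graph: nx.Graph, *, max_cliques: int = DEFAULT_MAX_CLIQUES
) -> list[frozenset]:
    """All maximal cliques, each once (Bron-Kerbosch with pivoting).

    ``max_cliques`` guards against pathological dense inputs; exceeding it
    raises :class:`CliqueLimitExceeded` rather than exhausting memory.
    """
    out: list[frozenset] = []
    for clique in nx.find_cliques(graph):
        out.append(frozenset(clique))
        if len(out) > max_cliques:
            raise CliqueLimitExceeded(
                f"more than {max_cliques} maximal cliques; raise max_cliques "
                "if this input is intentional"
            )
    return out


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _overlap_components(cliques: Sequence[frozenset], k: int) -> list[list[int]]:
    """Components of the clique-overlap graph (edges: shared nodes >= k-1)."""
    from collections import defaultdict

    node_to_cliques: dict = defaultdict(list)
    for idx, c in enumerate(cliques):
        for v in c:
            node_to_cliques[v].append(idx)

    uf = _UnionFind(len(cliques))
    if k == 2:
        # overlap >= 1: sharing any node suffices, no intersections needed
        for members in node_to_cliques.values():
            first = members[0]
            for j in members[1:]:
                uf.union(first, j)
    else:
        for idx, c in enumerate(cliques):
            seen: set[int] = set()
            for v in c:
                for j in node_to_cliques[v]:
                    if j <= idx or j in seen:
                        continue
                    seen.add(j)
                    if uf.find(idx) != uf.find(j) and len(c & cliques[j]) >= k - 1:
                        uf.union(idx, j)

    groups: dict = defaultdict(list)
    for idx in range(len(cliques)):
        groups[uf.find(idx)].append(idx)
    return list(groups.values())


def k_clique_communities(
    graph: nx.Graph,
    k: int,
    *,
    cliques: Sequence[frozenset] | None = None,
    max_cliques: int = DEFAULT_MAX_CLIQUES,
) -> KCliqueCommunitySet:
    """k-clique percolation communities of ``graph``.

    ``cliques`` may pass in precomputed maximal cliques (as returned by
    :func:`enumerate_maximal_cliques`) to amortize enumeration across k.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if cliques is None:
        cliques = enumerate_maximal_cliques(graph, max_cliques=max_cliques)
    big = [c for c in cliques if len(c) >= k]
    comms = []
    for component in _overlap_components(big, k):
        nodes: set = set()
        for idx in component:
            nodes |= big[idx]
        comms.append(frozenset(nodes))
    comms.sort(key=lambda c: (-len(c), sorted(map(str, c))))
    return KCliqueCommunitySet(k=k, communities=tuple(comms))


def percolation_profile(
    graph: nx.Graph,
    k_max: int,
    *,
    cliques: Sequence[frozenset] | None = None,
    max_cliques: int = DEFAULT_MAX_CLIQUES,
) -> PercolationProfile:
    """f_cc(k) for k = 2..k_max; f_cc(k) = 0 where no k-clique exists.

    Maximal cliques are enumerated once and reused for every k.
    """
    if k_max < 2:
        raise ValueError(f"k_max must be >= 2, got {k_max}")
    n = graph.number_of_nodes()
    if cliques is None:
        cliques = enumerate_maximal_cliques(graph, max_cliques=max_cliques)
    entries: dict[int, float] = {}
    unions: dict[int, float] = {}
    sizes: dict[int, int] = {}
    counts: dict[int, int] = {}
    for k in range(2, k_max + 1):
        comms = k_clique_communities(graph, k, cliques=cliques)
        sizes[k] = comms.largest_size
        counts[k] = len(comms)
        entries[k] = comms.largest_size / n if n else 0.0
        unions[k] = len(comms.node_union()) / n if n else 0.0
    return PercolationProfile(
        entries=entries,
        n_nodes=n,
        union_fractions=unions,
        largest_sizes=sizes,
        n_communities=counts,
    )


def critical_k(profile: PercolationProfile, min_fraction: float = 0.01) -> int:
    """Largest k with f_cc(k) >= min_fraction; 1 if no k qualifies.

    The cutoff operationalizes "percolation exists": the default 0.01 asks
    the largest community to cover at least 1% of the nodes.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if not profile.entries:
        raise ValueError("profile is empty")
    qualifying = [k for k, f in profile.entries.items() if f >= min_fraction]
    return max(qualifying) if qualifying else 1


def pc_threshold(n_nodes: int, k: int) -> float:
    """Analytic Erdos-Renyi k-clique percolation threshold 1/[N(k-1)]^(1/(k-1))."""
    if n_nodes < 2:
        raise ValueError(f"n_nodes must be >= 2, got {n_nodes}")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    return 1.0 / (n_nodes * (k - 1)) ** (1.0 / (k - 1))


def write_communities(
    comms: KCliqueCommunitySet, path: str | Path, *, fmt: str = "text"
) -> None:
    """Write communities as text (header ``k=<k>``, one community per line) or JSON."""
    path = Path(path)
    if fmt == "text":
        lines = [f"k={comms.k}"]
        for c in comms.communities:
            lines.append(" ".join(sorted(map(str, c))))
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        payload = {
            "k": comms.k,
            "communities": [sorted(map(str, c)) for c in comms.communities],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_profile(profile: PercolationProfile, path: str | Path) -> None:
    """Write a profile as TSV: k, f_cc, largest_community_size, n_communities."""
    lines = ["k\tf_cc\tlargest_community_size\tn_communities"]
    for k in profile.k_values:
        lines.append(
            f"{k}\t{profile.entries[k]:.6f}\t{profile.largest_sizes.get(k, 0)}"
            f"\t{profile.n_communities.get(k, 0)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
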