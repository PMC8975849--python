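"""Per-edge clique statistics and the weight-clustering relation.

The edge clustering coefficient of an edge (i, j),

    C_ij = N_T(ij) / (min(k_i, k_j) - 1),

is the number of triangles through the edge normalized by the maximum
possible given the endpoint degrees; like the node clustering coefficient it
lies in [0, 1].  In free-association networks C_ij correlates positively with
the association strength w_ij, approximately log-linearly; the relation is
estimated by sorting edges by C_ij, splitting into b equal-size bins, and
regressing log<w> on <c> over bin means.  The *edge k-clique number* is the
size of the largest clique containing the edge, at least 2 always.

C_ij is defined as 0 when min(k_i, k_j) = 1: no triangle through the edge is
possible there and the normalizing denominator would vanish.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import json

import networkx as nx
import numpy as np
import pandas as pd

from .assoc_network_io import is_weighted
from .clique_percolation import enumerate_maximal_cliques

__all__ = [
    "BinFit",
    "edge_clustering",
    "edge_clique_number",
    "edge_statistics_table",
    "bin_and_fit",
    "clique_number_distribution",
    "write_bin_fit",
]


@dataclass(frozen=True)
class BinFit:
    """Least-squares line of log<w_ij> against <c_ij> over b equal-size bins."""

    b: int
    bin_means: tuple[tuple[float, float], ...]  # (<c_ij>, <w_ij>) per bin
    slope: float
    intercept: float
    log_base: float

    def predict_weight(self, c: float) -> float:
        return float(self.log_base ** (self.slope * c + self.intercept))


def _require_edge(graph: nx.Graph, edge: tuple) -> tuple:
    u, v = edge
    if not graph.has_edge(u, v):
        raise ValueError(f"edge ({u!r}, {v!r}) not in network")
    return u, v


def edge_clustering(graph: nx.Graph, edge: tuple) -> float:
    """C_ij = (triangles through the edge) / (min degree - 1); 0 if min degree is 1."""
    u, v = _require_edge(graph, edge)
    md = min(graph.degree(u), graph.degree(v))
    if md <= 1:
        return 0.0
    n_tri = len(set(graph[u]) & set(graph[v]))
    return n_tri / (md - 1)


def edge_clique_number(graph: nx.Graph, edge: tuple) -> int:
    """Size of the largest clique containing the edge (>= 2).

    Computed on the subgraph induced by the common neighborhood: a clique
    containing both endpoints is the endpoints plus a clique of common
    neighbors.
    """
    u, v = _require_edge(graph, edge)
    common = set(graph[u]) & set(graph[v])
    if not common:
        return 2
    sub = graph.subgraph(common)
    return 2 + max(len(c) for c in nx.find_cliques(sub))


def edge_statistics_table(graph: nx.Graph) -> pd.DataFrame:
    """Per-edge statistics for every edge, as a DataFrame.

    Columns: source, target, weight (NaN when unweighted), n_triangles,
    edge_clustering, clique_number.  Clique numbers come from a single pass
    over the maximal cliques (each edge lies in at least one), which is far
    cheaper than per-edge enumeration on large graphs.
    """
    best: dict[tuple, int] = {}
    for clique in enumerate_maximal_cliques(graph):
        s = len(clique)
        if s < 2:
            continue
        members = sorted(clique, key=str)
        for i, a in enumerate(members):
            for c in members[i + 1 :]:
                key = (a, c) if str(a) <= str(c) else (c, a)
                if best.get(key, 0) < s:
                    best[key] = s

    rows = []
    for u, v, data in graph.edges(data=True):
        key = (u, v) if str(u) <= str(v) else (v, u)
        n_tri = len(set(graph[u]) & set(graph[v]))
        rows.append(
            {
                "source": key[0],
                "target": key[1],
                "weight": data.get("weight", np.nan),
                "n_triangles": n_tri,
                "edge_clustering": edge_clustering(graph, (u, v)),
                "clique_number": best.get(key, 2),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "source",
            "target",
            "weight",
            "n_triangles",
            "edge_clustering",
            "clique_number",
        ],
    )
    return frame.sort_values(["source", "target"], ignore_index=True)


def bin_and_fit(graph: nx.Graph, b: int = 100, log_base: float = 10.0) -> BinFit:
    """Bin edges by C_ij and fit log<w> = slope * <c> + intercept over bin means.

    Edges are sorted by (C_ij, source, target) — the id tie-break keeps the
    binning deterministic — and split into b contiguous near-equal bins, any
    remainder spread over the first bins.  The fit is an unweighted least
    squares over the b bin means.  Requires a weighted graph with >= b edges.
    """
    if not is_weighted(graph):
        raise ValueError("bin_and_fit requires a weighted network")
    if b < 2:
        raise ValueError(f"b must be >= 2, got {b}")
    m = graph.number_of_edges()
    if m < b:
        raise ValueError(f"need at least b={b} edges, got {m}")

    records = []
    for u, v, data in graph.edges(data=True):
        a, c = (u, v) if str(u) <= str(v) else (v, u)
        records.append((edge_clustering(graph, (u, v)), str(a), str(c), data["weight"]))
    records.sort()

    cvals = np.array([r[0] for r in records])
    wvals = np.array([r[3] for r in records])
    bin_means = []
    for idx in np.array_split(np.arange(m), b):
        bin_means.append((float(cvals[idx].mean()), float(wvals[idx].mean())))

    x = np.array([bm[0] for bm in bin_means])
    y = np.log([bm[1] for bm in bin_means]) / np.log(log_base)
    slope, intercept = np.polyfit(x, y, 1)
    return BinFit(
        b=b,
        bin_means=tuple(bin_means),
        slope=float(slope),
        intercept=float(intercept),
        log_base=float(log_base),
    )


def clique_number_distribution(
    graph: nx.Graph, weight_class: Callable[[float], bool]
) -> tuple[dict[int, float], float]:
    """Normalized clique-number histogram over edges whose weight satisfies the predicate.

    Returns ``(histogram, class_fraction)`` where the histogram maps clique
    number to the fraction of in-class edges and ``class_fraction`` is the
    class's share of all edges.  An empty class yields an empty histogram with
    a warning.
    """
    if not is_weighted(graph):
        raise ValueError("clique_number_distribution requires a weighted network")
    table = edge_statistics_table(graph)
    mask = table["weight"].map(weight_class)
    selected = table[mask]
    total = len(table)
    frac = len(selected) / total if total else 0.0
    if selected.empty:
        warnings.warn("weight class matches no edges", stacklevel=2)
        return {}, frac
    counts = selected["clique_number"].value_counts(normalize=True)
    return {int(k): float(v) for k, v in counts.sort_index().items()}, frac


def write_bin_fit(fit: BinFit, path: str | Path) -> None:
    payload = {
        "b": fit.b,
        "log_base": fit.log_base,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "bin_means": [{"c": c, "w": w} for c, w in fit.bin_means],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
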