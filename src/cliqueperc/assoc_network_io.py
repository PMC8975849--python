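"""Reading, validating, symmetrizing and summarizing weighted association networks.

Free-association datasets are directed cue->response tables where the strength
of a record is the fraction of respondents who produced that response, i.e. the
conditional probability of the response given the cue.  Analysis here runs on
the undirected projection: a cue-response pair linked in either direction
becomes one undirected edge carrying the larger of the two directed strengths.

Graphs are plain :class:`networkx.Graph` objects; edge weights, when present,
live in the ``"weight"`` edge attribute and must fall in (0, 1].  Node ids are
opaque strings compared exactly (no case folding), so distinct word forms are
never merged silently.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "AssociationTable",
    "SummaryStats",
    "read_edge_list",
    "write_edge_list",
    "read_association_table",
    "symmetrize",
    "network_summary",
    "write_summary",
]


@dataclass(frozen=True)
class AssociationTable:
    """Directed cue->response records with strengths in (0, 1].

    ``records`` is a list of ``(cue, response, strength)`` triples.  The
    validator enforces positive strengths <= 1 and uniqueness of (cue,
    response) pairs; it only *warns* when a cue's outgoing strengths sum to
    more than 1 (plus tolerance), since rounding in published norms can push
    the sum slightly over.
    """

    records: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        outgoing: dict[str, float] = {}
        for cue, response, strength in self.records:
            if not 0.0 < strength <= 1.0:
                raise ValueError(
                    f"strength for ({cue!r}, {response!r}) must be in (0, 1], "
                    f"got {strength}"
                )
            pair = (cue, response)
            if pair in seen:
                raise ValueError(f"duplicate record for ({cue!r}, {response!r})")
            seen.add(pair)
            outgoing[cue] = outgoing.get(cue, 0.0) + strength
        for cue, total in outgoing.items():
            if total > 1.0 + 1e-6:
                warnings.warn(
                    f"outgoing strengths of cue {cue!r} sum to {total:.4f} > 1",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SummaryStats:
    """Structural summary of an undirected network.

    ``density`` is E / (N(N-1)/2); ``transitivity`` is the global clustering
    coefficient 3*triangles/triples; ``avg_clustering`` is the mean local
    clustering coefficient with degree-<2 nodes contributing 0.
    """

    n_nodes: int
    n_edges: int
    density: float
    transitivity: float
    avg_clustering: float

    def to_dict(self) -> dict:
        return asdict(self)


def _validate_weight(w: float, context: str) -> None:
    if not 0.0 < w <= 1.0:
        raise ValueError(f"weight must be in (0, 1], got {w} ({context})")


def read_edge_list(
    path: str | Path,
    *,
    delimiter: str | None = None,
    header: bool = False,
) -> nx.Graph:
    """Read an undirected (optionally weighted) edge list.

    Rows have two or three columns ``source, target[, weight]``; the delimiter
    is auto-detected (tab or comma) unless given.  Lines starting with ``#``
    and blank lines are skipped.  Duplicate unordered pairs collapse keeping
    the maximum weight, consistent with the symmetrization rule; self-loops
    are rejected.  A file without a weight column yields an unweighted graph.
    """
    path = Path(path)
    graph = nx.Graph()
    weighted: bool | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if delimiter is None:
                delimiter = "\t" if "\t" in line else ","
            fields = [f.strip() for f in line.split(delimiter)]
            if header:  # first non-comment line is the header
                header = False
                continue
            if len(fields) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(fields)}"
                )
            row_weighted = len(fields) == 3
            if weighted is None:
                weighted = row_weighted
            elif weighted != row_weighted:
                raise ValueError(f"{path}:{lineno}: inconsistent column count")
            u, v = fields[0], fields[1]
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop on {u!r}")
            if row_weighted:
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: malformed weight {fields[2]!r}"
                    ) from exc
                _validate_weight(w, f"{path}:{lineno}")
                if graph.has_edge(u, v):
                    graph[u][v]["weight"] = max(graph[u][v]["weight"], w)
                else:
                    graph.add_edge(u, v, weight=w)
            else:
                graph.add_edge(u, v)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path, *, delimiter: str = "\t") -> None:
    """Write an edge list as TSV/CSV, with a weight column iff the graph is weighted."""
    path = Path(path)
    weighted = is_weighted(graph)
    with path.open("w") as fh:
        for u, v, data in graph.edges(data=True):
            if weighted:
                fh.write(f"{u}{delimiter}{v}{delimiter}{data['weight']:.12g}\n")
            else:
                fh.write(f"{u}{delimiter}{v}\n")


def is_weighted(graph: nx.Graph) -> bool:
    """True iff every edge carries a ``weight`` attribute (vacuously false on E=0)."""
    if graph.number_of_edges() == 0:
        return False
    return all("weight" in d for _, _, d in graph.edges(data=True))


def read_association_table(path: str | Path) -> AssociationTable:
    """Read a cue,response,strength CSV (with header) into an AssociationTable."""
    frame = pd.read_csv(path, dtype={"cue": str, "response": str})
    expected = {"cue", "response", "strength"}
    if not expected.issubset(frame.columns):
        raise ValueError(f"association table needs columns {sorted(expected)}")
    records = tuple(
        (str(r.cue), str(r.response), float(r.strength))
        for r in frame.itertuples(index=False)
    )
    return AssociationTable(records)


def symmetrize(table: AssociationTable) -> nx.Graph:
    """Undirected projection of a directed association table.

    Every unordered pair present in either direction becomes one edge whose
    weight is the maximum of the directed strengths (the greatest weight is
    attributed to a bidirectional association).  The node set is all cues and
    responses; an empty table yields an empty graph.
    """
    graph = nx.Graph()
    for cue, response, strength in table.records:
        graph.add_node(cue)
        graph.add_node(response)
        if cue == response:
            raise ValueError(f"self-association on {cue!r}")
        if graph.has_edge(cue, response):
            graph[cue][response]["weight"] = max(graph[cue][response]["weight"], strength)
        else:
            graph.add_edge(cue, response, weight=strength)
    return graph


def network_summary(graph: nx.Graph) -> SummaryStats:
    """Node/edge counts, density, transitivity and mean local clustering.

    Transitivity is 3*triangles / connected triples; average clustering is the
    mean over all nodes of the local clustering coefficient, with nodes of
    degree < 2 contributing 0 (the standard convention).  Requires >= 2 nodes.
    """
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("network summary needs at least 2 nodes")
    e = graph.number_of_edges()
    return SummaryStats(
        n_nodes=n,
        n_edges=e,
        density=e / (n * (n - 1) / 2),
        transitivity=nx.transitivity(graph),
        avg_clustering=nx.average_clustering(graph, count_zeros=True),
    )


def write_summary(stats: SummaryStats, path: str | Path) -> None:
    Path(path).write_text(json.dumps(stats.to_dict(), indent=2) + "\n")
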