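"""Perturbation protocols: weight thresholding and node removal, then percolation.

Two threshold experiments probe the role of association strength.  A *weak*
filter with threshold tau deletes every link of weight < tau, keeping the
strong-association subgraph; a *strong* filter with threshold theta deletes
every link of weight >= theta, keeping the weak-association subgraph.  The
strict/non-strict pairing makes the two outputs a partition of the edge set
at equal cutoff.  Node-removal experiments delete floor(alpha*N) nodes either
uniformly at random or by smallest degree (ties broken at random), keeping
surviving isolated nodes in the graph so that f_cc stays a fraction of the
perturbed node set.

``perturbation_sweep`` runs a grid of cutoffs or removal fractions, computes
the percolation profile after each perturbation, and for stochastic modes
repeats over seeds derived deterministically from a master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .assoc_network_io import is_weighted
from .clique_percolation import PercolationProfile, percolation_profile

__all__ = [
    "SweepSpec",
    "PerturbationResult",
    "threshold_filter",
    "remove_nodes",
    "perturbation_sweep",
    "derive_seeds",
]

_MODES = ("tau", "theta", "alpha_random", "alpha_degree")
_STOCHASTIC = ("alpha_random", "alpha_degree")


@dataclass(frozen=True)
class SweepSpec:
    """A perturbation experiment: which knob, which grid, how deep to percolate.

    ``mode`` is one of tau (weak filter), theta (strong filter), alpha_random,
    alpha_degree.  ``n_seeds`` only matters for the stochastic alpha modes
    (degree ties in alpha_degree are randomized too).
    """

    mode: str
    values: tuple[float, ...]
    k_max: int = 6
    n_seeds: int = 10
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if list(self.values) != sorted(self.values):
            raise ValueError("parameter grid must be sorted ascending")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


@dataclass(frozen=True)
class PerturbationResult:
    """Profiles per parameter value (and per seed for stochastic modes)."""

    parameter_name: str
    parameter_values: tuple[float, ...]
    profiles: dict[float, tuple[PercolationProfile, ...]]
    seeds: tuple[int, ...]

    def mean_f_cc(self, value: float, k: int) -> float:
        runs = self.profiles[value]
        return float(np.mean([p.entries[k] for p in runs]))

    def to_frame(self) -> pd.DataFrame:
        """Long format: parameter, value, seed, k, f_cc (seed NaN for deterministic modes)."""
        rows = []
        for value in self.parameter_values:
            for run_idx, profile in enumerate(self.profiles[value]):
                seed = self.seeds[run_idx] if self.seeds else np.nan
                for k in profile.k_values:
                    rows.append(
                        {
                            "parameter": self.parameter_name,
                            "value": value,
                            "seed": seed,
                            "k": k,
                            "f_cc": profile.entries[k],
                        }
                    )
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def threshold_filter(graph: nx.Graph, mode: str, cutoff: float) -> nx.Graph:
    """Filter edges by weight; the node set is unchanged.

    mode="weak" removes edges with w < cutoff (keeps strong links);
    mode="strong" removes edges with w >= cutoff (keeps the weak subgraph).
    """
    if mode not in ("weak", "strong"):
        raise ValueError(f"mode must be 'weak' or 'strong', got {mode!r}")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    if not is_weighted(graph):
        raise ValueError("threshold_filter requires a weighted network")
    out = nx.Graph()
    out.add_nodes_from(graph.nodes)
    for u, v, data in graph.edges(data=True):
        w = data["weight"]
        keep = w >= cutoff if mode == "weak" else w < cutoff
        if keep:
            out.add_edge(u, v, weight=w)
    return out


def remove_nodes(
    graph: nx.Graph, mode: str, alpha: float, seed: int | None = None
) -> nx.Graph:
    """Remove floor(alpha*N) nodes, uniformly at random or smallest-degree first.

    Degree ties in mode="lowest_degree" are broken uniformly at random under
    ``seed``.  Surviving nodes that lose all their edges stay in the graph.
    """
    if mode not in ("random", "lowest_degree"):
        raise ValueError(f"mode must be 'random' or 'lowest_degree', got {mode!r}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    rng = np.random.default_rng(seed)
    nodes = list(graph.nodes)
    n_remove = math.floor(alpha * len(nodes))
    if n_remove == 0:
        return graph.copy()
    if mode == "random":
        doomed = rng.choice(len(nodes), size=n_remove, replace=False)
        doomed_nodes = [nodes[i] for i in doomed]
    else:
        tiebreak = rng.permutation(len(nodes))
        order = sorted(range(len(nodes)), key=lambda i: (graph.degree(nodes[i]), tiebreak[i]))
        doomed_nodes = [nodes[i] for i in order[:n_remove]]
    out = graph.copy()
    out.remove_nodes_from(doomed_nodes)
    return out


def derive_seeds(master_seed: int, n: int) -> tuple[int, ...]:
    """n deterministic sub-seeds (< 2^31) from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return tuple(int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n))


def perturbation_sweep(graph: nx.Graph, spec: SweepSpec) -> PerturbationResult:
    """Apply the perturbation over the grid and profile percolation after each.

    Deterministic modes (tau, theta) run once per value; stochastic modes run
    ``spec.n_seeds`` replicates per value with seeds derived from
    ``spec.master_seed``.
    """
    stochastic = spec.mode in _STOCHASTIC
    seeds = derive_seeds(spec.master_seed, spec.n_seeds) if stochastic else ()
    profiles: dict[float, tuple[PercolationProfile, ...]] = {}
    for value in spec.values:
        runs = []
        if spec.mode == "tau":
            perturbed = threshold_filter(graph, "weak", value)
            runs.append(percolation_profile(perturbed, spec.k_max))
        elif spec.mode == "theta":
            perturbed = threshold_filter(graph, "strong", value)
            runs.append(percolation_profile(perturbed, spec.k_max))
        else:
            removal = "random" if spec.mode == "alpha_random" else "lowest_degree"
            for seed in seeds:
                perturbed = remove_nodes(graph, removal, value, seed)
                runs.append(percolation_profile(perturbed, spec.k_max))
        profiles[value] = tuple(runs)
    return PerturbationResult(
        parameter_name=spec.mode,
        parameter_values=tuple(spec.values),
        profiles=profiles,
        seeds=seeds,
    )
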