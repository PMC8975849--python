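"""Edge clustering coefficient, edge clique numbers, and the weight-clustering fit."""

from __future__ import annotations

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from cliqueperc import (
    assign_synthetic_weights,
    bin_and_fit,
    clique_number_distribution,
    edge_clique_number,
    edge_clustering,
    edge_statistics_table,
)

from conftest import oracle_k_cliques, random_graph


class TestEdgeClustering:
    @pytest.mark.parametrize("n", [3, 4, 6])
    def test_complete_graph_edges_fully_clustered(self, n):
        g = nx.complete_graph(n)
        assert edge_clustering(g, (0, 1)) == pytest.approx(1.0)

    def test_degree_one_endpoint_gives_zero(self):
        g = nx.path_graph(3)
        assert edge_clustering(g, (0, 1)) == 0.0

    def test_missing_edge_rejected(self, triangle):
        with pytest.raises(ValueError):
            edge_clustering(triangle, (0, 99))

    def test_matches_common_neighbor_oracle_on_random_graph(self):
        g = random_graph(20, 0.3, seed=4)
        for u, v in g.edges:
            common = len(set(g[u]) & set(g[v]))
            md = min(g.degree(u), g.degree(v))
            expected = 0.0 if md <= 1 else common / (md - 1)
            assert edge_clustering(g, (u, v)) == pytest.approx(expected)
            assert 0.0 <= edge_clustering(g, (u, v)) <= 1.0


class TestEdgeCliqueNumber:
    def test_isolated_pair_is_two(self):
        g = nx.Graph([("a", "b")])
        assert edge_clique_number(g, ("a", "b")) == 2

    def test_planted_k5_in_sparse_graph(self):
        g = nx.complete_graph(5)
        g.add_edges_from([(0, 10), (10, 11), (11, 12)])
        assert edge_clique_number(g, (0, 1)) == 5
        assert edge_clique_number(g, (10, 11)) == 2

    def test_matches_brute_force_on_random_graph(self):
        g = random_graph(15, 0.4, seed=8)
        for u, v in g.edges:
            best = 2
            for k in range(3, 16):
                if any({u, v} <= c for c in oracle_k_cliques(g, k)):
                    best = k
            assert edge_clique_number(g, (u, v)) == best

    def test_at_least_three_iff_edge_in_triangle(self):
        g = random_graph(18, 0.25, seed=3)
        for u, v in g.edges:
            has_triangle = bool(set(g[u]) & set(g[v]))
            assert (edge_clique_number(g, (u, v)) >= 3) == has_triangle

    def test_table_agrees_with_per_edge_calls(self):
        g = assign_synthetic_weights(random_graph(20, 0.3, seed=1), seed=0)
        table = edge_statistics_table(g)
        for row in table.itertuples(index=False):
            assert row.clique_number == edge_clique_number(g, (row.source, row.target))
            assert row.edge_clustering == pytest.approx(
                edge_clustering(g, (row.source, row.target))
            )


def graph_with_exact_law(slope=5.0, intercept=-4.4, n=40, p=0.25, seed=6):
    """Weights generated noiselessly from the log-linear rule on edge clustering."""
    g = random_graph(n, p, seed)
    return assign_synthetic_weights(g, slope, intercept, noise_sd=0.0, seed=0)


class TestBinAndFit:
    def test_recovers_noiseless_line_exactly(self):
        # singleton bins, and a line that stays inside (0, 1] for all C so the
        # clipping in the weight generator never engages
        g = graph_with_exact_law(slope=4.0, intercept=-5.0)
        fit = bin_and_fit(g, b=g.number_of_edges())
        assert fit.slope == pytest.approx(4.0, abs=1e-9)
        assert fit.intercept == pytest.approx(-5.0, abs=1e-9)

    def test_coarse_bins_recover_noiseless_line_approximately(self):
        # averaging w arithmetically within mixed-C bins introduces a small
        # convexity bias, so coarse binning is only approximate
        g = graph_with_exact_law(slope=4.0, intercept=-5.0)
        fit = bin_and_fit(g, b=10)
        assert fit.slope == pytest.approx(4.0, abs=0.5)
        assert fit.intercept == pytest.approx(-5.0, abs=0.5)

    def test_two_bins_match_hand_computed_line(self):
        # 4 edges in two 2-edge bins; line through the two bin-mean points
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.1)
        g.add_edge("c", "d", weight=0.2)
        g.add_edge("e", "f", weight=0.4)
        g.add_edge("g", "h", weight=0.8)
        # all C_ij = 0 -> make clustering differ via triangles
        g.add_edge("e", "x", weight=0.5)
        g.add_edge("f", "x", weight=0.5)
        g.add_edge("g", "y", weight=0.5)
        g.add_edge("h", "y", weight=0.5)
        fit = bin_and_fit(g, b=2)
        cvals = {(u, v): 0.0 for u, v in g.edges}
        # sorted by C then edge id; verify bin means against direct averages
        import numpy as np

        recs = sorted(
            (
                ( # same sort key construction as the module
                    len(set(g[u]) & set(g[v])) / (min(g.degree(u), g.degree(v)) - 1)
                    if min(g.degree(u), g.degree(v)) > 1
                    else 0.0,
                    min(u, v),
                    max(u, v),
                    g[u][v]["weight"],
                )
                for u, v in g.edges
            )
        )
        half = len(recs) // 2
        c1 = np.mean([r[0] for r in recs[:half]])
        w1 = np.mean([r[3] for r in recs[:half]])
        c2 = np.mean([r[0] for r in recs[half:]])
        w2 = np.mean([r[3] for r in recs[half:]])
        slope = (math.log10(w2) - math.log10(w1)) / (c2 - c1)
        intercept = math.log10(w1) - slope * c1
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)

    def test_invariant_to_edge_input_order(self):
        g = graph_with_exact_law(seed=9)
        h = nx.Graph()
        h.add_nodes_from(g.nodes)
        for u, v, d in sorted(g.edges(data=True), key=lambda e: str(e[:2]), reverse=True):
            h.add_edge(u, v, **d)
        fit_g = bin_and_fit(g, b=8)
        fit_h = bin_and_fit(h, b=8)
        assert fit_g.slope == pytest.approx(fit_h.slope)
        assert fit_g.bin_means == fit_h.bin_means

    def test_rejects_unweighted_or_too_few_edges(self):
        with pytest.raises(ValueError):
            bin_and_fit(nx.complete_graph(5), b=4)
        with pytest.raises(ValueError):
            bin_and_fit(graph_with_exact_law(n=10, p=0.2, seed=1), b=1000)

    def test_natural_log_base_round_trips(self):
        g = random_graph(30, 0.3, seed=2)
        g = assign_synthetic_weights(g, 2.0, -3.0, 0.0, log_base=math.e, seed=0)
        fit = bin_and_fit(g, b=g.number_of_edges(), log_base=math.e)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(-3.0, abs=1e-9)


class TestCliqueNumberDistribution:
    def test_single_triangle_all_mass_at_three(self, triangle):
        g = assign_synthetic_weights(triangle, noise_sd=0.0, seed=0)
        hist, frac = clique_number_distribution(g, lambda w: True)
        assert hist == {3: 1.0}
        assert frac == 1.0

    def test_empty_class_warns(self, weighted_fixture):
        with pytest.warns(UserWarning):
            hist, frac = clique_number_distribution(weighted_fixture, lambda w: w > 2)
        assert hist == {}
        assert frac == 0.0

    def test_planted_strong_clique_and_weak_periphery(self):
        g = nx.Graph()
        for u, v in combinations(range(5), 2):  # strong K5
            g.add_edge(u, v, weight=0.5)
        for i in range(5, 15):  # weak triangle-free chain
            g.add_edge(i, i + 1, weight=0.005)
        strong, strong_frac = clique_number_distribution(g, lambda w: w > 0.1)
        weak, weak_frac = clique_number_distribution(g, lambda w: w <= 0.01)
        assert strong == {5: 1.0}
        assert weak == {2: 1.0}
        assert strong_frac + weak_frac == pytest.approx(1.0)
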