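"""Hamming-1 graph, intracloud robustness, meta-graph and accessibility."""

from __future__ import annotations

import numpy as np
import pytest

import sdclouds as sc
from sdclouds.mutgraph import (
    GraphError,
    MAX_DEGREE,
    giant_fraction_histogram,
    hamming_neighbors,
    meta_matrices,
)


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def make_graph(values: dict[str, float], members: dict[int, list[str]]):
    etr_map = sc.EtrMap(values)
    table = sc.CloudTable(members, etr_map)
    return sc.build_hamming_graph(etr_map, table)


class TestSequenceGraph:
    def test_complete_core_set_is_18_regular(self, hamming_graph):
        degrees = [d for _, d in hamming_graph.degree]
        assert max(degrees) == MAX_DEGREE == 18
        assert min(degrees) == 18
        assert hamming_graph.number_of_edges() == 36864

    def test_distance_two_pair_is_not_adjacent(self):
        G = make_graph(
            {"AAAAAA": 0.1, "AAAACC": 0.2},
            {0: ["AAAAAA"], 1: ["AAAACC"]},
        )
        assert G.number_of_edges() == 0

    def test_edges_match_pairwise_distance_recount(self, hamming_graph):
        rng = np.random.default_rng(0)
        nodes = list(hamming_graph.nodes)
        for _ in range(500):
            u, v = rng.choice(nodes, 2, replace=False)
            assert hamming_graph.has_edge(u, v) == (hamming(u, v) == 1)

    def test_neighbor_enumeration_is_exact(self):
        nbs = list(hamming_neighbors("AAAAAA"))
        assert len(nbs) == 18
        assert all(hamming("AAAAAA", n) == 1 for n in nbs)

    def test_unlabeled_nodes_excluded_from_cloud_analyses(self):
        etr_map = sc.EtrMap({"AAAAAA": 0.1, "AAAAAC": 0.2, "AAAAAG": 0.3})
        table = sc.CloudTable({0: ["AAAAAA", "AAAAAC"]}, etr_map)
        G = sc.build_hamming_graph(etr_map, table)
        assert G.nodes["AAAAAG"]["cloud"] is None
        metrics = sc.intracloud_metrics(G)
        assert list(metrics["label"]) == [0]


class TestIntracloudMetrics:
    def test_singleton_cloud(self):
        metrics = sc.intracloud_metrics(
            make_graph({"AAAAAA": 0.1}, {0: ["AAAAAA"]})
        )
        row = metrics.iloc[0]
        assert row["n_nodes"] == 1
        assert row["n_edges"] == 0
        assert row["giant_fraction"] == 1.0
        assert row["avg_shortest_path_giant"] == 0.0

    def test_two_adjacent_cores(self):
        metrics = sc.intracloud_metrics(
            make_graph(
                {"AAAAAA": 0.1, "AAAAAC": 0.2}, {0: ["AAAAAA", "AAAAAC"]}
            )
        )
        row = metrics.iloc[0]
        assert row["n_components"] == 1
        assert row["giant_fraction"] == 1.0
        assert row["avg_degree"] == 1.0

    def test_two_isolated_cores(self):
        metrics = sc.intracloud_metrics(
            make_graph(
                {"AAAAAA": 0.1, "CCCCCC": 0.2}, {0: ["AAAAAA", "CCCCCC"]}
            )
        )
        row = metrics.iloc[0]
        assert row["n_components"] == 2
        assert row["giant_fraction"] == 0.5

    def test_giant_path_cap_yields_nan(self, landscape, binned_clouds):
        G = sc.build_hamming_graph(landscape, binned_clouds)
        metrics = sc.intracloud_metrics(G, max_path_nodes=1)
        big = metrics[metrics["giant_size"] > 1]
        assert big["avg_shortest_path_giant"].isna().all()

    def test_histogram_is_plot_ready(self, landscape, binned_clouds):
        G = sc.build_hamming_graph(landscape, binned_clouds)
        metrics = sc.intracloud_metrics(G, max_path_nodes=1)
        hist = giant_fraction_histogram(metrics)
        assert hist["count"].sum() == len(metrics)
        singles = metrics[metrics["n_nodes"] == 1]
        assert (singles["giant_fraction"] == 1.0).all()


class TestMetaGraph:
    def test_unbridged_clouds_have_no_meta_edge(self):
        G = make_graph(
            {"AAAAAA": 0.1, "CCCCCC": 0.2},
            {0: ["AAAAAA"], 1: ["CCCCCC"]},
        )
        meta = sc.build_meta_graph(G)
        assert meta.number_of_edges() == 0

    def test_bridge_stats_hand_values(self):
        # two bridges between clouds 0 and 1 with |dETR| 0.1 and 0.3
        G = make_graph(
            {
                "AAAAAA": 0.1,
                "AAAAAC": 0.2,  # bridge 1: |0.2-0.1| = 0.1
                "TTTTTT": 0.5,
                "TTTTTA": 0.8,  # bridge 2: |0.8-0.5| = 0.3
            },
            {0: ["AAAAAA", "TTTTTT"], 1: ["AAAAAC", "TTTTTA"]},
        )
        meta = sc.build_meta_graph(G)
        e = meta.edges[0, 1]
        assert e["bridge_count"] == 2
        assert e["mean_abs_detr"] == pytest.approx(0.2)

    def test_matrices_are_symmetric(self, landscape, binned_clouds):
        G = sc.build_hamming_graph(landscape, binned_clouds)
        counts, detr = meta_matrices(G, order="label")
        assert (counts.to_numpy() == counts.to_numpy().T).all()
        d = detr.to_numpy()
        mask = ~np.isnan(d)
        assert (mask == mask.T).all()
        assert np.allclose(d[mask], d.T[mask])


class TestTransitionMatrix:
    def test_single_cloud_is_the_identity(self):
        G = make_graph(
            {"AAAAAA": 0.1, "AAAAAC": 0.2}, {0: ["AAAAAA", "AAAAAC"]}
        )
        P = sc.transition_matrix(G)
        assert np.allclose(P.to_numpy(), [[1.0]])

    def test_rows_are_stochastic(self, landscape, binned_clouds):
        G = sc.build_hamming_graph(landscape, binned_clouds)
        P = sc.transition_matrix(G)
        assert np.allclose(P.to_numpy().sum(axis=1), 1.0, atol=1e-12)
        assert (P.to_numpy() >= 0).all()

    def test_total_directed_moves_is_twice_edge_count(
        self, landscape, binned_clouds
    ):
        from sdclouds.mutgraph import _directed_moves

        G = sc.build_hamming_graph(landscape, binned_clouds)
        n_moves = sum(1 for _ in _directed_moves(G))
        assert n_moves == 2 * G.number_of_edges()

    def test_singleton_source_cloud_always_leaves(self, landscape):
        """A singleton cloud inside the full core set: all 18 moves exit."""
        cores = landscape.cores
        members = {0: ["AAAAAA"], 1: [c for c in cores if c != "AAAAAA"]}
        table = sc.CloudTable(members, landscape)
        G = sc.build_hamming_graph(landscape, table)
        P = sc.transition_matrix(G)
        assert P.loc[0, 0] == 0.0
        assert P.loc[0, 1] == 1.0

    def test_cloud_without_moves_is_an_error(self):
        G = make_graph({"AAAAAA": 0.1}, {0: ["AAAAAA"]})
        with pytest.raises(GraphError, match="zero outgoing"):
            sc.transition_matrix(G)


class TestBeneficialFractions:
    def test_flat_landscape_has_no_beneficial_moves(self):
        G = make_graph(
            {"AAAAAA": 0.5, "AAAAAC": 0.5, "AAAAAG": 0.5},
            {0: ["AAAAAA", "AAAAAC"], 1: ["AAAAAG"]},
        )
        B = sc.beneficial_fractions(G)
        assert np.nansum(B.to_numpy()) == 0.0

    def test_single_bridge_directionality(self):
        G = make_graph(
            {"AAAAAA": 0.1, "AAAAAC": 0.2},
            {0: ["AAAAAA"], 1: ["AAAAAC"]},
        )
        B = sc.beneficial_fractions(G)
        assert B.loc[0, 1] == 1.0  # uphill
        assert B.loc[1, 0] == 0.0  # downhill

    def test_complementary_counting(self, landscape, binned_clouds):
        """fraction(i->j) + fraction(j->i) + ties = 1 over a bridge set."""
        from sdclouds.mutgraph import _directed_moves

        G = sc.build_hamming_graph(landscape, binned_clouds)
        B = sc.beneficial_fractions(G)
        up, total = {}, {}
        for cu, cv, d in _directed_moves(G):
            total[(cu, cv)] = total.get((cu, cv), 0) + 1
            if d > 0:
                up[(cu, cv)] = up.get((cu, cv), 0) + 1
        items = list(total.items())[:50]
        for (i, j), n in items:
            assert B.loc[i, j] == pytest.approx(up.get((i, j), 0) / n)
            ties = n - up.get((i, j), 0) - up.get((j, i), 0)
            assert B.loc[i, j] + B.loc[j, i] + ties / n == pytest.approx(1.0)

    def test_zero_move_pairs_are_missing(self):
        G = make_graph(
            {"AAAAAA": 0.1, "CCCCCC": 0.9},
            {0: ["AAAAAA"], 1: ["CCCCCC"]},
        )
        B = sc.beneficial_fractions(G)
        assert np.isnan(B.loc[0, 1])


class TestMonotonePaths:
    def test_source_equals_target(self):
        G = make_graph(
            {"AAAAAA": 0.1, "AAAAAC": 0.2},
            {0: ["AAAAAA"], 1: ["AAAAAC"]},
        )
        res = sc.monotone_paths(G, 0, 0)
        assert res.reachable and res.shortest_length == 0

    def test_increasing_chain_is_reachable(self):
        # AAAAAA -> AAAAAC -> AAAACC, strictly increasing ETR
        G = make_graph(
            {"AAAAAA": 0.1, "AAAAAC": 0.2, "AAAACC": 0.3},
            {0: ["AAAAAA"], 1: ["AAAAAC"], 2: ["AAAACC"]},
        )
        res = sc.monotone_paths(G, 0, 2, strict=True)
        assert res.reachable
        assert res.shortest_length == 2
        assert res.witness_path == ("AAAAAA", "AAAAAC", "AAAACC")

    def test_decreasing_path_is_inaccessible(self):
        G = make_graph(
            {"AAAAAA": 0.5, "AAAAAC": 0.3, "AAAACC": 0.1},
            {0: ["AAAAAA"], 1: ["AAAACC"]},
        )
        # the middle node is cloudless but still on the graph
        res = sc.monotone_paths(G, 1, 0)
        assert res.reachable  # uphill direction works
        res_down = sc.monotone_paths(G, 0, 1)
        assert not res_down.reachable
        assert res_down.witness_path is None

    def test_witness_etr_is_monotone(self, landscape, binned_clouds):
        G = sc.build_hamming_graph(landscape, binned_clouds)
        labels = binned_clouds.labels
        res = sc.monotone_paths(G, labels[0], labels[-1])
        if res.reachable and res.shortest_length:
            etrs = [G.nodes[n]["etr"] for n in res.witness_path]
            assert all(a <= b for a, b in zip(etrs, etrs[1:]))

    def test_unknown_cloud_rejected(self, hamming_graph):
        with pytest.raises(GraphError):
            sc.monotone_paths(hamming_graph, 0, 1)
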