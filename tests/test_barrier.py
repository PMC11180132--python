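"""Cell-graph construction, shortest-path enumeration and barrier metrics
against hand-worked and BFS oracles."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import cytoplex as cx
from cytoplex import barrier, scenes


def cells_df(coords, types):
    return pd.DataFrame({"cell_id": [f"c{i}" for i in range(len(coords))],
                         "label": list(types),
                         "x": [c[0] for c in coords],
                         "y": [c[1] for c in coords]})


def to_networkx(g):
    G = nx.Graph()
    G.add_nodes_from(range(g.n_nodes))
    G.add_edges_from(g.edges())
    return G


class TestBuildGraph:
    def test_triangle(self):
        g = barrier.build_graph(cells_df([(0, 0), (10, 0), (0, 10)], "AAA"))
        assert g.n_edges == 3

    def test_square_grid_prunes_diagonal(self):
        # 2x2 unit grid (10 µm spacing), max length 12: sides kept, diagonal cut
        g = barrier.build_graph(cells_df([(0, 0), (10, 0), (0, 10), (10, 10)],
                                         "AAAA"), max_edge_length=12.0)
        edges = set(g.edges())
        assert len(edges) == 4
        assert (0, 3) not in edges and (1, 2) not in edges

    def test_collinear_points_become_path_graph(self):
        g = barrier.build_graph(cells_df([(0, 0), (10, 0), (20, 0), (30, 0)],
                                         "AAAA"))
        assert sorted(g.edges()) == [(0, 1), (1, 2), (2, 3)]

    def test_two_points_single_edge(self):
        g = barrier.build_graph(cells_df([(0, 0), (5, 5)], "AB"))
        assert sorted(g.edges()) == [(0, 1)]

    def test_duplicate_coordinates_handled(self):
        g = barrier.build_graph(cells_df([(0, 0), (0, 0), (10, 0)], "ABA"))
        assert g.n_nodes == 3 and g.n_edges >= 2

    def test_no_self_edges_and_retained_below_max(self, rng):
        pts = rng.uniform(0, 300, size=(80, 2))
        g = barrier.build_graph(cells_df(pts, "A" * 80), max_edge_length=50.0)
        for i, j in g.edges():
            assert i != j
            assert np.hypot(*(pts[i] - pts[j])) <= 50.0

    def test_knn_mode(self):
        pts = [(0, 0), (1, 0), (2, 0), (50, 0)]
        g = barrier.build_graph(cells_df(pts, "AAAA"), method="knn", k=1)
        assert (0, 1) in set(g.edges())

    def test_single_cell_rejected(self):
        with pytest.raises(cx.ValidationError):
            barrier.build_graph(cells_df([(0, 0)], "A"))


class TestBarrierMetrics:
    def test_path_graph_s_b_t(self):
        """S–B–T: one intermediate, of the barrier type, adjacent to T."""
        df = cells_df([(0, 0), (10, 0), (20, 0)], ["S", "B", "T"])
        g = barrier.build_graph(df)
        rec = barrier.score_barrier(g, "S", "B", "T")
        r = rec.iloc[0]
        assert r["path_length"] == 2 and r["n_paths"] == 1
        assert r["barrier_count"] == 1 and r["barrier_fraction"] == 1.0
        assert r["adjacent_count"] == 1 and r["adjacent_fraction"] == 1.0
        assert r["all_paths_adjacent_fraction"] == 1.0

    def test_source_adjacent_to_target_no_intermediates(self):
        df = cells_df([(0, 0), (10, 0)], ["S", "T"])
        g = barrier.build_graph(df)
        r = barrier.score_barrier(g, "S", "B", "T").iloc[0]
        assert r["path_length"] == 1
        assert r["barrier_count"] == 0 and r["barrier_fraction"] == 0.0
        assert r["adjacent_fraction"] == 0.0

    def test_diamond_all_paths_average_half(self):
        """S–{X,B}–T diamond: two shortest paths; the all-paths fractions
        average the barrier (1.0) and non-barrier (0.0) routes to 0.5."""
        df = cells_df([(0.0, 0.0), (10.0, 8.0), (10.0, -8.0), (20.0, 0.0)],
                      ["S", "X", "B", "T"])
        g = barrier.build_graph(df, max_edge_length=15.0)
        assert sorted(g.edges()) == [(0, 1), (0, 2), (1, 3), (2, 3)]
        r = barrier.score_barrier(g, "S", "B", "T").iloc[0]
        assert r["n_paths"] == 2
        assert r["all_paths_barrier_fraction"] == pytest.approx(0.5)
        assert r["all_paths_adjacent_fraction"] == pytest.approx(0.5)
        # single-path metrics use the lexicographically first path (via X)
        assert r["barrier_fraction"] in (0.0, 1.0)

    def test_no_barrier_cells_all_zero(self, rng):
        pts = rng.uniform(0, 200, size=(50, 2))
        types = ["S"] * 10 + ["T"] * 10 + ["X"] * 30
        g = barrier.build_graph(cells_df(pts, types))
        rec = barrier.score_barrier(g, "S", "B", "T")
        reach = rec[rec["reachable"]]
        for m in ("barrier_count", "barrier_fraction", "adjacent_fraction",
                  "all_paths_barrier_fraction", "all_paths_adjacent_fraction"):
            assert (reach[m] == 0).all()

    def test_unreachable_sources_flagged_and_excluded(self):
        df = cells_df([(0, 0), (10, 0), (500, 500), (510, 500)],
                      ["S", "B", "T", "T"])
        g = barrier.build_graph(df, max_edge_length=50.0)
        rec = barrier.score_barrier(g, "S", "B", "T")
        assert not rec["reachable"].iloc[0]
        summ = barrier.summarise(rec, "img")
        assert (summ["n_reachable"] == 0).all()
        assert summ["mean"].isna().all()

    def test_no_targets_noted(self):
        df = cells_df([(0, 0), (10, 0)], ["S", "B"])
        g = barrier.build_graph(df)
        rec = barrier.score_barrier(g, "S", "B", "T")
        assert not rec["reachable"].any()

    def test_off_path_barrier_cells_do_not_change_metrics(self):
        """Adding barrier cells away from every shortest path leaves the
        source's metrics unchanged (locality)."""
        base = [(0.0, 0.0), (10.0, 0.0), (20.0, 0.0)]
        df1 = cells_df(base, ["S", "B", "T"])
        df2 = cells_df(base + [(0.0, 40.0), (10.0, 40.0)],
                       ["S", "B", "T", "B", "B"])
        g1 = barrier.build_graph(df1, max_edge_length=15.0)
        g2 = barrier.build_graph(df2, max_edge_length=15.0)
        r1 = barrier.score_barrier(g1, "S", "B", "T").iloc[0]
        r2 = barrier.score_barrier(g2, "S", "B", "T").iloc[0]
        for m in ("path_length", "barrier_count", "barrier_fraction",
                  "adjacent_fraction", "all_paths_adjacent_fraction"):
            assert r1[m] == r2[m]

    def test_shortest_path_lengths_match_networkx_oracle(self, rng):
        pts = rng.uniform(0, 600, size=(300, 2))
        types = rng.choice(["S", "B", "T", "X"], size=300, p=[0.2, 0.2, 0.2, 0.4])
        g = barrier.build_graph(cells_df(pts, types), max_edge_length=60.0)
        rec = barrier.score_barrier(g, "S", "B", "T")
        G = to_networkx(g)
        targets = set(np.flatnonzero(g.types == "T"))
        for _, row in rec.iterrows():
            s = int(np.flatnonzero(g.cell_ids == row["cell_id"])[0])
            lengths = nx.single_source_shortest_path_length(G, s)
            best = min((lengths[t] for t in targets if t in lengths),
                       default=None)
            if best is None:
                assert not row["reachable"]
            else:
                assert row["reachable"] and row["path_length"] == best

    def test_target_cluster_filter_restricts_targets(self):
        # two target nodes, only one allowed
        df = cells_df([(0, 0), (10, 0), (0, 10)], ["S", "T", "T"])
        g = barrier.build_graph(df)
        rec = barrier.score_barrier(g, "S", "B", "T",
                                    allowed_target_ids=["c1"])
        assert rec.iloc[0]["path_length"] == 1
        rec_none = barrier.score_barrier(g, "S", "B", "T",
                                         allowed_target_ids=[])
        assert not rec_none.iloc[0]["reachable"]


class TestSummaries:
    def _records(self, fracs):
        rows = []
        for i, f in enumerate(fracs):
            rows.append({"cell_id": f"c{i}", "source_type": "S",
                         "barrier_type": "B", "target_type": "T",
                         "reachable": True, "path_length": 2, "n_paths": 1,
                         "path_types": "S;B;T",
                         **{m: f for m in barrier._METRICS}})
        return pd.DataFrame(rows)

    def test_single_record_degenerate_stats(self):
        s = barrier.summarise(self._records([1.0]), "img")
        row = s[s["metric"] == "all_paths_adjacent_fraction"].iloc[0]
        assert row["mean"] == row["median"] == 1.0 and row["std"] == 0.0

    def test_population_std_formula(self):
        s = barrier.summarise(self._records([0.0, 1.0]), "img")
        row = s[s["metric"] == "barrier_fraction"].iloc[0]
        assert row["mean"] == 0.5 and row["median"] == 0.5
        assert row["std"] == pytest.approx(0.5)   # population (n) form

    def test_idempotent_over_identical_records(self):
        s = barrier.summarise(self._records([0.7] * 5), "img")
        row = s[s["metric"] == "adjacent_fraction"].iloc[0]
        assert row["mean"] == pytest.approx(0.7) and row["std"] == 0.0

    def test_planted_annulus_scores_above_scattered_twin(self, barrier_scenes):
        scores = {}
        for with_annulus, df in barrier_scenes.items():
            g = barrier.build_graph(df, max_edge_length=50.0)
            rec = barrier.score_barrier(g, "CD8 T cells", "Fibroblasts",
                                        "Tumour")
            scores[with_annulus] = barrier.barrier_score(
                barrier.summarise(rec, "img"))
        assert scores[True] > scores[False]
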