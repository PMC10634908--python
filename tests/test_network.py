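"""Graph handling, localization tests and the phase-organization null."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest

import cyclenet as cn
from cyclenet import network


class TestLoadEdgeList:
    def test_dedup_and_self_loop_removal(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("#gene_a\tgene_b\na\tb\nb\ta\na\ta\n")
        g = cn.load_edge_list(p)
        assert g.number_of_edges() == 1
        assert g.number_of_nodes() == 2

    def test_triangle(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("a\tb\nb\tc\nc\ta\n")
        g = cn.load_edge_list(p)
        assert (g.number_of_nodes(), g.number_of_edges()) == (3, 3)
        assert nx.is_connected(g)

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("a\tb\nonly_one_column\n")
        with pytest.raises(ValueError, match=":2:"):
            cn.load_edge_list(p)

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("# nothing here\n")
        with pytest.raises(ValueError, match="empty"):
            cn.load_edge_list(p)


class TestLargestConnectedComponent:
    def test_connected_graph_is_itself(self):
        g = nx.path_graph(5)
        assert set(cn.largest_connected_component(g).nodes) == set(g.nodes)

    def test_triangle_beats_isolated_edge(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("x", "y")])
        assert set(cn.largest_connected_component(g).nodes) == {"a", "b", "c"}

    def test_size_tie_broken_lexicographically(self):
        g = nx.Graph([("b", "c"), ("a", "d")])
        assert set(cn.largest_connected_component(g).nodes) == {"a", "d"}


class TestGeodesicDistances:
    def test_path_graph(self):
        g = nx.path_graph(["a", "b", "c"])
        d = cn.geodesic_distances(g)
        assert d.at["a", "c"] == 2
        assert d.at["a", "a"] == 0
        assert (d.to_numpy() == d.to_numpy().T).all()

    def test_unknown_node_is_error(self):
        g = nx.path_graph(["a", "b"])
        with pytest.raises(KeyError, match="zz"):
            cn.geodesic_distances(g, sources=["zz"])

    def test_unreachable_is_infinite(self):
        g = nx.Graph([("a", "b"), ("x", "y")])
        assert np.isinf(cn.geodesic_distances(g, ["a"], ["x"]).at["a", "x"])

    def test_matches_networkx_all_pairs_oracle(self):
        g = nx.gnp_random_graph(200, 0.03, seed=9)
        got = cn.geodesic_distances(g)
        for u, lengths in nx.all_pairs_shortest_path_length(g):
            for v, d in lengths.items():
                assert got.at[u, v] == d


class TestSubsetSanityChecks:
    def test_representativeness_of_full_set(self):
        phases = np.array([1.0, 4.0, 9.0, 15.0, 22.0])
        res = cn.representativeness_test(phases, phases)
        assert res["p_value"] == 1.0

    def test_windowed_subset_detected(self):
        rng = np.random.default_rng(0)
        full = rng.uniform(0, 24, 400)
        window = full[(full >= 6) & (full < 12)]
        assert cn.representativeness_test(window, full)["p_value"] < 1e-4

    def test_degree_comparison_of_all_nodes(self, er_graph):
        res = cn.degree_comparison(er_graph, list(er_graph.nodes))
        assert res["statistic"] == 0.0

    def test_degree_comparison_flags_hubs(self, er_graph):
        deg = dict(er_graph.degree())
        hubs = sorted(deg, key=deg.get, reverse=True)[:50]
        assert cn.degree_comparison(er_graph, hubs)["p_value"] < 1e-6

    def test_degree_comparison_calibrated_on_random_subsets(self, er_graph):
        rng = np.random.default_rng(1)
        nodes = list(er_graph.nodes)
        ps = [cn.degree_comparison(er_graph,
                                   list(rng.choice(nodes, 60, replace=False))
                                   )["p_value"]
              for _ in range(40)]
        assert np.mean(np.array(ps) < 0.05) <= 0.1  # KS with ties is conservative

    def test_localization_of_planted_clique(self, er_graph):
        nodes = sorted(er_graph.nodes)
        clique = nodes[:10]
        g = er_graph.copy()
        g.add_edges_from((a, b) for i, a in enumerate(clique)
                         for b in clique[i + 1:])
        assert cn.localization_test(g, clique)["p_value"] < 1e-6

    def test_localization_of_everything_is_null(self, er_graph):
        res = cn.localization_test(er_graph, list(er_graph.nodes))
        assert 0.3 < res["p_value"] < 0.7

    def test_localization_calibrated_on_random_subsets(self, er_graph):
        rng = np.random.default_rng(2)
        nodes = list(er_graph.nodes)
        ps = [cn.localization_test(er_graph,
                                   list(rng.choice(nodes, 40, replace=False))
                                   )["p_value"]
              for _ in range(30)]
        assert np.mean(np.array(ps) < 0.05) <= 0.2
        assert np.median(ps) > 0.1

    def test_subset_outside_lcc_dropped(self, caplog):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("x", "y")])
        with caplog.at_level("WARNING"):
            with pytest.raises(ValueError, match="fewer than 2"):
                cn.localization_test(g, ["a", "x"])


class TestPhaseDistanceProfile:
    def test_identical_phases_give_zero_median(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        d = cn.geodesic_distances(g)
        phases = pd.Series(5.0, index=list(g.nodes))
        prof = cn.phase_distance_profile(d, phases, min_pairs=1)
        assert (prof["median_dphi"] == 0).all()

    def test_single_pair_profile(self):
        g = nx.Graph([("a", "b")])
        d = cn.geodesic_distances(g)
        prof = cn.phase_distance_profile(d, pd.Series({"a": 3.0, "b": 7.0}),
                                         min_pairs=1)
        assert len(prof) == 1
        assert prof.iloc[0]["distance"] == 1
        assert prof.iloc[0]["n_pairs"] == 1
        assert prof.iloc[0]["median_dphi"] == pytest.approx(4.0)

    def test_uniform_phases_median_near_six(self, er_graph):
        rng = np.random.default_rng(3)
        nodes = sorted(er_graph.nodes)
        d = cn.geodesic_distances(er_graph, nodes, nodes)
        phases = pd.Series(rng.uniform(0, 24, len(nodes)), index=nodes)
        prof = cn.phase_distance_profile(d, phases, min_pairs=200)
        assert not prof.empty
        assert np.allclose(prof["median_dphi"], 6.0, atol=0.5)

    def test_sparse_classes_dropped(self):
        g = nx.path_graph([f"n{i}" for i in range(6)])
        d = cn.geodesic_distances(g)
        phases = pd.Series(np.arange(6, dtype=float), index=list(g.nodes))
        prof = cn.phase_distance_profile(d, phases, min_pairs=3)
        assert (prof["n_pairs"] >= 3).all()


class TestMedianTrend:
    def test_exact_line(self):
        prof = pd.DataFrame({"distance": [1, 2, 3], "n_pairs": 10,
                             "median_dphi": [2.0, 3.0, 4.0]})
        res = cn.median_trend(prof)
        assert res["slope"] == pytest.approx(1.0)

    def test_flat_profile_convention(self):
        prof = pd.DataFrame({"distance": [1, 2, 3], "n_pairs": 10,
                             "median_dphi": [2.0, 2.0, 2.0]})
        res = cn.median_trend(prof)
        assert res["slope"] == 0.0
        assert res["p_value"] == 1.0

    def test_too_few_classes_is_error(self):
        prof = pd.DataFrame({"distance": [1, 2], "n_pairs": 10,
                             "median_dphi": [2.0, 3.0]})
        with pytest.raises(ValueError, match="3 distance classes"):
            cn.median_trend(prof)

    def test_planted_trend_recovered(self):
        rng = np.random.default_rng(4)
        x = np.arange(1, 8)
        y = 2.0 + 0.5 * x + rng.normal(0, 0.05, x.size)
        prof = pd.DataFrame({"distance": x, "n_pairs": 100, "median_dphi": y})
        res = cn.median_trend(prof)
        assert res["slope"] == pytest.approx(0.5, abs=0.1)
        assert res["p_value"] < 0.01


class TestPermutationNull:
    def test_degenerate_equal_phases_give_p_one(self, er_graph):
        nodes = sorted(er_graph.nodes)[:80]
        phases = pd.Series(9.0, index=nodes)
        res = cn.permutation_null(er_graph, nodes, phases, n_perm=100,
                                  seed=0, min_pairs=5)
        assert all(p == 1.0 for p in res.empirical_p.values())

    def test_deterministic_given_seed(self, er_graph):
        rng = np.random.default_rng(5)
        nodes = sorted(er_graph.nodes)[:60]
        phases = pd.Series(rng.uniform(0, 24, 60), index=nodes)
        r1 = cn.permutation_null(er_graph, nodes, phases, n_perm=50, seed=7,
                                 min_pairs=5)
        r2 = cn.permutation_null(er_graph, nodes, phases, n_perm=50, seed=7,
                                 min_pairs=5)
        assert np.array_equal(r1.null_medians, r2.null_medians, equal_nan=True)
        assert r1.empirical_p == r2.empirical_p

    def test_add_one_estimator_bounds(self, er_graph):
        rng = np.random.default_rng(6)
        nodes = sorted(er_graph.nodes)[:60]
        phases = pd.Series(rng.uniform(0, 24, 60), index=nodes)
        res = cn.permutation_null(er_graph, nodes, phases, n_perm=200, seed=8,
                                  min_pairs=5)
        for p in res.empirical_p.values():
            assert 1 / 201 <= p <= 1.0

    def test_null_mean_matches_all_pairs_median(self, er_graph):
        """Uniform placement: null medians centre on the phase multiset's
        all-pairs median."""
        rng = np.random.default_rng(7)
        nodes = sorted(er_graph.nodes)[:100]
        phi = rng.uniform(0, 24, 100)
        phases = pd.Series(phi, index=nodes)
        res = cn.permutation_null(er_graph, nodes, phases, n_perm=400, seed=9,
                                  min_pairs=20)
        iu = np.triu_indices(100, k=1)
        overall = np.median(cn.phase_difference(phi[iu[0]], phi[iu[1]]))
        for j in range(res.null_medians.shape[1]):
            col = res.null_medians[:, j]
            assert abs(np.nanmean(col) - overall) < 0.5

    def test_planted_organization_detected(self, er_graph):
        truth = cn.plant_phases(er_graph, 0.2, 0.9, 20, seed=11)
        cyc = truth.loc[truth.is_cycling, "gene_id"].tolist()
        phases = truth.set_index("gene_id").loc[cyc, "phase_true"]
        res = cn.permutation_null(er_graph, cyc, phases, n_perm=200, seed=12,
                                  min_pairs=10)
        d1 = int(res.profile["distance"].iloc[0])
        assert d1 == 1
        assert res.empirical_p[d1] < 0.05
        assert res.trend is not None and res.trend["slope"] > 0

    def test_cycling_node_outside_lcc_is_error(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("x", "y")])
        phases = pd.Series({"a": 1.0, "x": 2.0})
        with pytest.raises(ValueError, match="outside the LCC"):
            cn.permutation_null(g, ["a", "x"], phases, n_perm=10, min_pairs=1)

    def test_two_sided_option(self, er_graph):
        rng = np.random.default_rng(13)
        nodes = sorted(er_graph.nodes)[:60]
        phases = pd.Series(rng.uniform(0, 24, 60), index=nodes)
        res = cn.permutation_null(er_graph, nodes, phases, n_perm=100, seed=14,
                                  min_pairs=5, alternative="two-sided")
        for p in res.empirical_p.values():
            assert 0 < p <= 1.0
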