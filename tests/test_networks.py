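import networkx as nx
import numpy as np
import pytest

import graph_oracles as oracle
from contactscape.networks import (FeatureInterval, build_network,
                                   closeness_centrality, clustering_coefficient,
                                   degree_histogram, equalize_edges,
                                   map_contacts_to_features, node_metrics_table,
                                   read_edge_list, scale_free_fit,
                                   shortest_path_histogram, stress_distribution,
                                   stress_values, topological_coefficient,
                                   write_edge_list)
from contactscape.pair_filtering import Contact


def graph(*edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return g


TRIANGLE = graph(("a", "b"), ("b", "c"), ("a", "c"))
PATH3 = graph(("a", "b"), ("b", "c"))
STAR3 = graph(("hub", "x"), ("hub", "y"), ("hub", "z"))
CYCLE4 = graph((0, 1), (1, 2), (2, 3), (3, 0))


class TestFeatureMapping:
    FEATURES = [
        FeatureInterval("G1", "chr1", 100, 200, "GENE"),
        FeatureInterval("G2", "chr1", 4900, 5100, "GENE"),
        FeatureInterval("G3", "chr1", 140, 160, "GENE"),     # overlaps G1
        FeatureInterval("P1", "chr1", 150, 155, "PSEUDO"),   # excluded kind
    ]

    def test_containment_counts_pair(self):
        counts = map_contacts_to_features(
            [Contact("chr1", 150, "chr1", 5000)], self.FEATURES[:2])
        assert counts == {("G1", "G2"): 1}

    def test_end_outside_features_contributes_nothing(self):
        counts = map_contacts_to_features(
            [Contact("chr1", 90, "chr1", 5000)], self.FEATURES[:2])
        assert counts == {}

    def test_overlapping_features_all_incremented(self):
        counts = map_contacts_to_features(
            [Contact("chr1", 150, "chr1", 5000)], self.FEATURES)
        assert counts == {("G1", "G2"): 1, ("G2", "G3"): 1}

    def test_kind_filter_excludes_non_gene_entries(self):
        counts = map_contacts_to_features(
            [Contact("chr1", 151, "chr1", 5000)], self.FEATURES,
            node_kinds=("GENE", "PSEUDO"))
        assert ("G2", "P1") in counts

    def test_self_pairs_dropped(self):
        counts = map_contacts_to_features(
            [Contact("chr1", 110, "chr1", 190)], self.FEATURES[:1])
        assert counts == {}


class TestBuildNetwork:
    def test_strict_threshold(self):
        counts = {("G1", "G2"): 3, ("G1", "G3"): 1}
        g = build_network(counts, threshold=1)
        assert list(g.edges(data="weight")) == [("G1", "G2", 3)]
        assert "G3" not in g

    def test_threshold_zero_keeps_single_read_edges(self):
        counts = {("G1", "G2"): 3, ("G1", "G3"): 1}
        g = build_network(counts, threshold=0)
        assert g.number_of_edges() == 2

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        counts = {(f"a{i}", f"b{i}"): int(rng.integers(1, 20)) for i in range(40)}
        sizes = [build_network(counts, t).number_of_edges()
                 for t in range(0, 21)]
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[0] == 40 and sizes[-1] == 0


class TestEqualizeEdges:
    def test_exact_cut_at_threshold(self):
        counts = {("a", "b"): 5, ("a", "c"): 4, ("b", "c"): 3,
                  ("c", "d"): 2, ("d", "e"): 2, ("e", "f"): 1}
        (t, g), = equalize_edges({"s": counts}, 3).values()
        assert t == 2
        assert sorted(d for *_, d in g.edges(data="weight")) == [3, 4, 5]

    def test_tie_add_back_in_lexicographic_order(self):
        counts = {("a", "b"): 9, ("c", "d"): 1, ("a", "z"): 1,
                  ("b", "c"): 1, ("x", "y"): 1}
        (t, g), = equalize_edges({"s": counts}, 3).values()
        assert t == 1
        assert set(g.edges) == {("a", "b"), ("a", "z"), ("b", "c")}

    def test_target_equal_to_total_keeps_everything(self):
        counts = {("a", "b"): 2, ("b", "c"): 1}
        (t, g), = equalize_edges({"s": counts}, 2).values()
        assert t == 0 and g.number_of_edges() == 2

    def test_unreachable_target_is_error(self):
        with pytest.raises(ValueError, match="target"):
            equalize_edges({"s": {("a", "b"): 1}}, 5)

    def test_all_samples_get_exactly_target(self):
        rng = np.random.default_rng(1)
        samples = {}
        for depth, name in ((40, "lo"), (200, "hi")):
            samples[name] = {(f"g{i}", f"g{i + 1}"): int(rng.integers(1, depth))
                             for i in range(60)}
        out = equalize_edges(samples, 25)
        for t, g in out.values():
            assert g.number_of_edges() == 25


class TestStatisticsOnNamedGraphs:
    def test_degree_histograms(self):
        assert degree_histogram(TRIANGLE) == {2: 3}
        assert degree_histogram(STAR3) == {1: 3, 3: 1}

    def test_shortest_path_histograms(self):
        assert shortest_path_histogram(PATH3) == {1: 2, 2: 1}
        assert shortest_path_histogram(TRIANGLE) == {1: 3}

    def test_unreachable_pairs_absent(self):
        g = graph(("a", "b"), ("c", "d"))
        assert shortest_path_histogram(g) == {1: 2}

    def test_clustering(self):
        assert clustering_coefficient(TRIANGLE, "a") == 1.0
        assert clustering_coefficient(PATH3, "b") == 0.0
        hub_plus = graph(("h", "a"), ("h", "b"), ("h", "c"), ("a", "b"))
        assert clustering_coefficient(hub_plus, "h") == pytest.approx(1 / 3)

    def test_closeness(self):
        complete = nx.complete_graph(5)
        assert closeness_centrality(complete, 0) == pytest.approx(1.0)
        assert closeness_centrality(PATH3, "a") == pytest.approx(2 / 3)
        iso = graph(("a", "b"))
        iso.add_node("lonely")
        assert closeness_centrality(iso, "lonely") == 0.0

    def test_stress(self):
        assert stress_values(PATH3)["b"] == 1
        assert stress_values(STAR3)["hub"] == 3
        assert stress_values(TRIANGLE)["a"] == 0

    def test_stress_histogram_bins_by_powers_of_ten(self):
        g = nx.path_graph(30)  # interior nodes span stress values 29..225
        _, hist = stress_distribution(g)
        assert set(hist) <= {0, 1, 10, 100}
        assert sum(hist.values()) == 30

    def test_topological_coefficient(self):
        assert topological_coefficient(CYCLE4, 0) == pytest.approx(2 / 3)
        assert topological_coefficient(TRIANGLE, "a") == pytest.approx(1.0)
        assert topological_coefficient(STAR3, "x") == 0.0  # single neighbor


class TestAgainstBruteForceOracles:
    def test_all_statistics_match_on_random_graphs(self, random_graphs):
        for g in random_graphs(15, seed=3):
            assert degree_histogram(g) == oracle.degree_hist_oracle(g)
            assert shortest_path_histogram(g) == oracle.path_hist_oracle(g)
            stress = stress_values(g)
            for n in g.nodes:
                assert clustering_coefficient(g, n) \
                    == pytest.approx(oracle.clustering_oracle(g, n))
                assert closeness_centrality(g, n) \
                    == pytest.approx(oracle.closeness_oracle(g, n))
                assert stress[n] == oracle.stress_oracle(g, n)
                assert topological_coefficient(g, n) \
                    == pytest.approx(oracle.topological_oracle(g, n))

    def test_handshake_lemma(self, random_graphs):
        for g in random_graphs(10, seed=4):
            assert sum(d for _, d in g.degree) == 2 * g.number_of_edges()


class TestScaleFreeFit:
    def test_exact_power_law(self):
        slope, r2 = scale_free_fit({1: 64, 2: 16, 4: 4, 8: 1})
        assert slope == pytest.approx(-2.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_histogram_has_zero_slope(self):
        slope, r2 = scale_free_fit({1: 5, 2: 5, 4: 5})
        assert slope == pytest.approx(0.0)
        assert r2 == pytest.approx(1.0)

    def test_too_few_points_is_error(self):
        with pytest.raises(ValueError):
            scale_free_fit({1: 10, 2: 5})

    def test_preferential_attachment_looks_scale_free(self):
        slopes, r2s = [], []
        for seed in range(10):
            g = nx.barabasi_albert_graph(500, 2, seed=seed)
            s, r2 = scale_free_fit(degree_histogram(g))
            slopes.append(s)
            r2s.append(r2)
        assert all(s < -1 for s in slopes)
        assert np.mean(r2s) > 0.7


class TestTablesAndIO:
    def test_node_metrics_table_columns(self):
        df = node_metrics_table(TRIANGLE)
        assert list(df.columns) == ["id", "kind", "degree", "clustering",
                                    "closeness", "stress",
                                    "topological_coefficient"]
        assert (df["degree"] == 2).all()

    def test_edge_list_round_trip(self, tmp_path):
        counts = {("G1", "G2"): 3, ("T1", "G1"): 2}
        g = build_network(counts, kinds={"G1": "GENE", "G2": "GENE", "T1": "TFBS"})
        path = tmp_path / "edges.tsv"
        write_edge_list(g, path)
        back = read_edge_list(path)
        assert set(back.edges) == set(g.edges)
        assert back.nodes["T1"]["kind"] == "TFBS"

    def test_mixed_kind_network_keeps_kinds(self):
        features = [FeatureInterval("G1", "chr1", 100, 200, "GENE"),
                    FeatureInterval("T1", "chr1", 5000, 5100, "TFBS"),
                    FeatureInterval("G2", "chr1", 9000, 9900, "GENE")]
        contacts = [Contact("chr1", 150, "chr1", 5050),
                    Contact("chr1", 150, "chr1", 9100),
                    Contact("chr1", 5050, "chr1", 9100)]
        counts = map_contacts_to_features(contacts, features, ("GENE", "TFBS"))
        g = build_network(counts, kinds={"G1": "GENE", "G2": "GENE", "T1": "TFBS"})
        kinds = {g.nodes[n]["kind"] for n in g}
        assert kinds == {"GENE", "TFBS"}
        assert g.number_of_edges() == 3  # gene-gene, gene-TFBS and TFBS-gene edges coexist
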