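"""Network construction, centralities, hub testing, ego extraction."""

import itertools

import networkx as nx
import numpy as np
import pytest

from omicshub.corrnet import CorrelationEdge
from omicshub.graph import (NodeMetricsRecord, build_graph, ego_subnetwork,
                            hub_test, largest_component, node_metrics,
                            summarize_neighbors)
from omicshub.stats import AllZeroDifferencesError

from _oracles import exhaustive_metrics


def edges(*triples):
    return [CorrelationEdge(a, b, rho) for a, b, rho in triples]


def weighted_graph(edge_list):
    """Graph straight from (a, b, rho) triples without thresholding."""
    return build_graph(edges(*edge_list), threshold=0.0)


class TestBuildGraph:
    def test_threshold_and_sign_assignment(self):
        graph = build_graph(edges(("A", "B", 0.96), ("B", "C", -0.97),
                                  ("C", "D", 0.80)), threshold=0.95)
        assert set(graph.nodes) == {"A", "B", "C"}
        assert graph.number_of_edges() == 2
        assert graph.edges["B", "C"]["sign"] == "-"
        assert graph.edges["B", "C"]["weight"] == pytest.approx(0.97)

    def test_empty_and_all_below_threshold(self):
        assert build_graph([], threshold=0.95).number_of_nodes() == 0
        graph = build_graph(edges(("A", "B", 0.5)), threshold=0.95)
        assert graph.number_of_nodes() == 0

    def test_conflicting_duplicates_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            build_graph(edges(("A", "B", 0.96), ("A", "B", 0.97)), 0.95)
        # identical duplicates are tolerated
        graph = build_graph(edges(("A", "B", 0.96), ("A", "B", 0.96)), 0.95)
        assert graph.number_of_edges() == 1


class TestLargestComponent:
    def test_picks_bigger_component(self):
        graph = weighted_graph([("A", "B", 1), ("B", "C", 1), ("C", "D", 1),
                                ("D", "E", 1), ("X", "Y", 1)])
        assert set(largest_component(graph).nodes) == {"A", "B", "C", "D", "E"}

    def test_connected_graph_unchanged(self):
        graph = weighted_graph([("A", "B", 1), ("B", "C", 1)])
        out = largest_component(graph)
        assert nx.utils.graphs_equal(out, graph)

    def test_tie_breaks_to_smallest_member(self):
        graph = weighted_graph([("C", "D", 1), ("A", "B", 1)])
        assert set(largest_component(graph).nodes) == {"A", "B"}

    def test_empty_graph_passes_through(self):
        assert largest_component(nx.Graph()).number_of_nodes() == 0


class TestNodeMetrics:
    def metric(self, records, node):
        return next(r for r in records if r.feature_id == node)

    def test_path_graph_betweenness(self):
        records = node_metrics(weighted_graph([("A", "B", 1), ("B", "C", 1)]))
        assert self.metric(records, "B").betweenness == pytest.approx(1.0)
        assert self.metric(records, "A").betweenness == 0.0
        assert self.metric(records, "C").betweenness == 0.0

    def test_complete_graph_symmetry(self):
        triples = [(a, b, 1.0) for a, b in itertools.combinations("ABCD", 2)]
        records = node_metrics(weighted_graph(triples))
        assert all(r.degree == 3 for r in records)
        assert all(r.betweenness == 0.0 for r in records)

    def test_star_center(self):
        triples = [("hub", leaf, 1.0) for leaf in "ABCDE"]
        records = node_metrics(weighted_graph(triples))
        center = self.metric(records, "hub")
        assert center.degree == 5
        assert center.betweenness == pytest.approx(10.0)  # C(5,2) leaf pairs

    def test_distance_modes_differ(self):
        # strong edge A-B (0.9) vs weak path A-C-B (0.5 each)
        graph = weighted_graph([("A", "B", 0.9), ("A", "C", 0.5),
                                ("C", "B", 0.5)])
        inverse = node_metrics(graph, "inverse_weight")
        raw = node_metrics(graph, "raw_weight")
        # inverse: direct distance 1/0.9 < 2/0.5, C is never between
        assert self.metric(inverse, "C").betweenness == 0.0
        # raw: direct distance 0.9 < 1.0 via C, same topology here; closeness differs
        assert self.metric(inverse, "A").closeness != \
            self.metric(raw, "A").closeness

    def test_degree_is_unweighted(self):
        records = node_metrics(weighted_graph([("A", "B", 0.2), ("A", "C", 0.9)]))
        assert self.metric(records, "A").degree == 2

    def test_contract_errors(self):
        with pytest.raises(ValueError, match="empty"):
            node_metrics(nx.Graph())
        bad = nx.Graph()
        bad.add_edge("A", "B", weight=0.0, rho=0.0)
        with pytest.raises(ValueError, match="nonpositive"):
            node_metrics(bad)
        with pytest.raises(ValueError, match="distance_mode"):
            node_metrics(weighted_graph([("A", "B", 1)]), "euclidean")


@pytest.mark.parametrize("distance_mode", ["inverse_weight", "raw_weight"])
def test_metrics_match_exhaustive_enumeration(rng, distance_mode):
    # random weighted graphs with <= 7 vertices; weights are exact binary
    # fractions so shortest-path ties are detected without float ambiguity
    for _ in range(40):
        n = int(rng.integers(2, 8))
        graph = nx.Graph()
        graph.add_nodes_from(str(i) for i in range(n))
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.5:
                weight = float(rng.choice([0.25, 0.5, 1.0]))
                graph.add_edge(str(i), str(j), weight=weight, rho=weight)
        if graph.number_of_nodes() == 0:
            continue
        got = {r.feature_id: r for r in node_metrics(graph, distance_mode)}
        expected = {r.feature_id: r for r in exhaustive_metrics(graph, distance_mode)}
        for node in expected:
            assert got[node].degree == expected[node].degree
            assert got[node].closeness == pytest.approx(
                expected[node].closeness, abs=1e-9)
            assert got[node].betweenness == pytest.approx(
                expected[node].betweenness, abs=1e-9)


class TestHubTest:
    def records(self, values, focal_value, focal="focal"):
        recs = [NodeMetricsRecord(f"n{i}", int(v), float(v), float(v))
                for i, v in enumerate(values)]
        recs.append(NodeMetricsRecord(focal, int(focal_value),
                                      float(focal_value), float(focal_value)))
        return recs

    def test_symmetric_values_are_not_significant(self):
        values = [1, 2, 3, 4, 5, 7, 8, 9, 10, 11]  # symmetric around 6
        result = hub_test(self.records(values, 6), "focal", "closeness")
        assert result.p > 0.9
        assert result.direction == "none"
        assert result.network_pseudomedian == pytest.approx(6.0)

    def test_focal_above_all_gives_smallest_exact_p(self):
        values = list(range(1, 16))
        result = hub_test(self.records(values, 100), "focal", "closeness")
        assert result.p == pytest.approx(2 / 2**15)
        assert result.direction == "above"
        assert result.W == 0.0
        assert result.method == "exact"

    def test_needs_focal_and_enough_nodes(self):
        with pytest.raises(KeyError):
            hub_test(self.records(range(12), 5), "ghost", "degree")
        with pytest.raises(ValueError, match="at least 10"):
            hub_test(self.records(range(5), 3), "focal", "degree")
        with pytest.raises(ValueError, match="metric"):
            hub_test(self.records(range(12), 5), "focal", "pagerank")

    def test_all_zero_differences_signaled_distinctly(self):
        with pytest.raises(AllZeroDifferencesError):
            hub_test(self.records([4] * 12, 4), "focal", "closeness")


class TestEgoSubnetwork:
    def test_star_focal_center_returns_whole_graph(self):
        graph = weighted_graph([("hub", leaf, 1.0) for leaf in "ABCD"])
        ego = ego_subnetwork(graph, "hub")
        assert nx.utils.graphs_equal(ego, graph)

    def test_isolated_focal_single_vertex(self):
        graph = weighted_graph([("A", "B", 1.0)])
        graph.add_node("loner")
        assert set(ego_subnetwork(graph, "loner").nodes) == {"loner"}

    def test_triangle_with_pendant_keeps_neighbor_edges(self):
        graph = weighted_graph([("A", "B", 1), ("B", "C", 1), ("A", "C", 1),
                                ("C", "D", 1)])
        ego = ego_subnetwork(graph, "A")
        assert set(ego.nodes) == {"A", "B", "C"}
        assert ego.number_of_edges() == 3

    def test_missing_focal_rejected(self):
        with pytest.raises(KeyError):
            ego_subnetwork(weighted_graph([("A", "B", 1)]), "Z")


class TestSummarizeNeighbors:
    def test_sorted_ascending_by_rho(self):
        graph = weighted_graph([("F", "A", 0.9), ("F", "B", -0.8),
                                ("F", "C", 0.5), ("A", "B", 0.7)])
        table = summarize_neighbors(graph, "F")
        assert table["neighbor_id"].tolist() == ["B", "C", "A"]
        assert table["rho"].tolist() == [-0.8, 0.5, 0.9]

    def test_no_neighbors_gives_empty_table(self):
        graph = weighted_graph([("A", "B", 1.0)])
        graph.add_node("F")
        assert len(summarize_neighbors(graph, "F")) == 0

    def test_degree_neighbor_count_ego_size_consistency(self, rng):
        triples = [(f"n{i}", f"n{j}", float(rng.uniform(-1, 1)))
                   for i, j in itertools.combinations(range(10), 2)
                   if rng.random() < 0.4]
        if not triples:
            triples = [("n0", "n1", 0.5)]
        graph = weighted_graph([t for t in triples if t[2] != 0])
        focal = sorted(graph.nodes)[0]
        table = summarize_neighbors(graph, focal)
        assert len(table) == graph.degree(focal)
        assert len(table) == ego_subnetwork(graph, focal).number_of_nodes() - 1
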