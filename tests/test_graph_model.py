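"""Network parsing, undirected conversion, and spanning-tree primitives."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import complete_graph, path_graph, random_connected_graph, star_graph
from hubnet.graph_model import (
    GraphStructureError,
    InfeasibleSubset,
    NetworkFormatError,
    SignedEdge,
    SignedNetwork,
    SimpleGraph,
    SpanningTree,
    kruskal_from_subset,
    parse_network,
    to_undirected,
    total_pairwise_distance,
    tree_node_degrees,
)


class TestParseNetwork:
    def test_basic_triangle(self, tmp_path):
        f = tmp_path / "net.tsv"
        f.write_text("A\t+\tB\nB\t-\tC\nC\t+\tA\n")
        net = parse_network(f)
        assert net.nodes == ["A", "B", "C"]
        assert len(net.edges) == 3
        assert net.edges[1].sign == "-"

    def test_probability_column_and_tokens(self, tmp_path):
        f = tmp_path / "net.tsv"
        f.write_text("# comment\nA\tactivates\tB\t0.8\nB\tinhibits\tC\t0.25\n")
        net = parse_network(f)
        assert net.edges[0].p == pytest.approx(0.8)
        assert net.edges[0].sign == "+"
        assert net.edges[1].sign == "-"

    def test_probability_out_of_bounds(self, tmp_path):
        f = tmp_path / "net.tsv"
        f.write_text("A\t+\tB\t1.3\n")
        with pytest.raises(NetworkFormatError, match="outside"):
            parse_network(f)

    def test_malformed_row_reports_line(self, tmp_path):
        f = tmp_path / "net.tsv"
        f.write_text("A\t+\tB\nA\tB\n")
        with pytest.raises(NetworkFormatError, match="line 2"):
            parse_network(f)


class TestToUndirected:
    def test_reciprocal_edges_merge_max(self):
        net = SignedNetwork(
            nodes=["A", "B"],
            edges=[SignedEdge("A", "B", "+", 0.2), SignedEdge("B", "A", "-", 0.6)],
        )
        g = to_undirected(net)
        assert g.n_edges == 1
        assert g.probabilities[0] == pytest.approx(0.6)
        assert g.weights[0] == pytest.approx(0.4)

    @pytest.mark.parametrize("policy,expected", [
        ("max", 0.6), ("mean", 0.4), ("noisy-or", 1 - 0.8 * 0.4),
    ])
    def test_merge_policies(self, policy, expected):
        net = SignedNetwork(
            nodes=["A", "B"],
            edges=[SignedEdge("A", "B", "+", 0.2), SignedEdge("B", "A", "+", 0.6)],
        )
        g = to_undirected(net, probability_merge=policy)
        assert g.probabilities[0] == pytest.approx(expected)

    def test_self_loop_dropped(self):
        net = SignedNetwork(
            nodes=["A", "B"],
            edges=[SignedEdge("A", "A", "+", None), SignedEdge("A", "B", "+", None)],
        )
        g = to_undirected(net)
        assert g.n_edges == 1
        assert g.weights is None  # unweighted input stays unweighted

    def test_triangle_stays_triangle(self):
        net = SignedNetwork(
            nodes=["A", "B", "C"],
            edges=[SignedEdge("A", "B", "+"), SignedEdge("B", "C", "+"),
                   SignedEdge("C", "A", "+")],
        )
        g = to_undirected(net)
        assert g.n_edges == 3
        assert g.is_connected()

    def test_edge_count_never_grows(self):
        rng = random.Random(7)
        for _ in range(20):
            n = rng.randint(2, 8)
            labels = [f"n{i}" for i in range(n)]
            edges = [
                SignedEdge(rng.choice(labels), rng.choice(labels), "+", None)
                for _ in range(rng.randint(1, 20))
            ]
            net = SignedNetwork(nodes=labels, edges=edges)
            g = to_undirected(net)
            assert g.n_edges <= len(edges)


class TestTotalPairwiseDistance:
    def test_path_of_three(self):
        g = path_graph(3)
        t = kruskal_from_subset(g, [1, 2])
        assert total_pairwise_distance(t) == 8  # unordered 1+1+2 doubled

    def test_star_of_four(self):
        g = star_graph(4)
        t = kruskal_from_subset(g, [1, 2, 3])
        assert total_pairwise_distance(t) == 18  # 2 * (n-1)^2

    def test_single_node(self):
        g = SimpleGraph(nodes=["a"], edges=[])
        t = kruskal_from_subset(g, [])
        assert total_pairwise_distance(t) == 0

    @pytest.mark.parametrize("n", range(2, 13))
    def test_closed_forms(self, n):
        # ordered-pair sums: path 2 n(n^2-1)/6, star 2 (n-1)^2
        p = path_graph(n)
        tp = kruskal_from_subset(p, list(range(1, n)))
        assert total_pairwise_distance(tp) == 2 * n * (n * n - 1) // 6
        s = star_graph(n)
        ts = kruskal_from_subset(s, list(range(1, n)))
        assert total_pairwise_distance(ts) == 2 * (n - 1) ** 2


class TestKruskalFromSubset:
    def test_tree_subset_is_identity(self):
        g = complete_graph(4)
        t = kruskal_from_subset(g, [1, 2, 3])
        assert t.edge_indices == (1, 2, 3)

    def test_cycle_edge_rejected_in_subset_order(self):
        g = SimpleGraph(nodes=list("abc"), edges=[(0, 1), (1, 2), (0, 2)])
        t = kruskal_from_subset(g, [1, 2, 3])
        assert t.edge_indices == (1, 2)

    def test_weighted_mode_prefers_light_edges(self):
        g = SimpleGraph(nodes=list("abc"), edges=[(0, 1), (1, 2), (0, 2)],
                        weights=[0.9, 0.1, 0.2], probabilities=[0.1, 0.9, 0.8])
        t = kruskal_from_subset(g, [1, 2, 3], weighted=True)
        assert t.edge_indices == (2, 3)

    def test_uncovered_node_reported(self):
        g = complete_graph(4)
        # edges 1..3 are (0,1),(0,2),(0,3); subset {(0,1)} misses v2, v3
        report = kruskal_from_subset(g, [1])
        assert isinstance(report, InfeasibleSubset)
        assert "v2" in report.uncovered_nodes and "v3" in report.uncovered_nodes

    def test_duplicate_index_rejected(self):
        g = complete_graph(4)
        with pytest.raises(NetworkFormatError, match="duplicate"):
            kruskal_from_subset(g, [1, 1, 2])

    def test_rerun_is_bit_identical(self):
        rng = random.Random(3)
        g = random_connected_graph(7, rng)
        subset = rng.sample(range(1, g.n_edges + 1), g.n_edges - 1)
        t1 = kruskal_from_subset(g, subset)
        t2 = kruskal_from_subset(g, subset)
        assert t1.edge_indices == t2.edge_indices

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_subsets_yield_valid_trees(self, seed):
        """Any feasible subset must extract a genuine spanning tree."""
        rng = random.Random(seed)
        g = random_connected_graph(rng.randint(3, 8), rng)
        k = rng.randint(g.n_nodes - 1, g.n_edges)
        subset = rng.sample(range(1, g.n_edges + 1), k)
        t = kruskal_from_subset(g, subset)
        if isinstance(t, InfeasibleSubset):
            return
        assert len(t.edge_indices) == g.n_nodes - 1
        degs = tree_node_degrees(t)
        assert sum(degs.values()) == 2 * (g.n_nodes - 1)
        # connected + acyclic follows from N-1 edges and BFS reaching all
        assert total_pairwise_distance(t) == t.total_distance


class TestTreeNodeDegrees:
    def test_star_degrees(self):
        g = star_graph(4)
        t = kruskal_from_subset(g, [1, 2, 3])
        degs = tree_node_degrees(t)
        assert degs["v0"] == 3
        assert all(degs[f"v{i}"] == 1 for i in (1, 2, 3))

    def test_path_degrees(self):
        g = path_graph(3)
        t = kruskal_from_subset(g, [1, 2])
        assert list(tree_node_degrees(t).values()) == [1, 2, 1]
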