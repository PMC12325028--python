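import numpy as np
import pytest

from umhl import (
    FCMatrix,
    Subnetwork,
    assign_to_centers,
    average_degree,
    bipartition_bfs,
    choose_split_seeds,
    recursive_partition,
    select_centers,
    threshold_adjacency,
)
from umhl.local import BinaryAdjacency

from conftest import random_fc
from reference_partition import reference_partition


def fc_from_edges(n, edges, strong=0.9, weak=0.05):
    """FC matrix whose |entries| >= 0.5 exactly on the given edge set."""
    f = np.full((n, n), weak)
    for a, b in edges:
        f[a, b] = f[b, a] = strong
    np.fill_diagonal(f, 1.0)
    return FCMatrix(values=f)


def path_graph_sub(n):
    edges = frozenset((i, i + 1) for i in range(n - 1))
    return Subnetwork(vertex_ids=tuple(range(n)), internal_edges=edges, center=0)


class TestThreshold:
    def test_absolute_value_rule(self):
        f = np.eye(3)
        f[0, 1] = f[1, 0] = 0.9
        f[0, 2] = f[2, 0] = -0.8
        f[1, 2] = f[2, 1] = 0.1
        adj = threshold_adjacency(FCMatrix(values=f), t=0.5)
        assert adj.values[0, 1] == 1 and adj.values[0, 2] == 1
        assert adj.values[1, 2] == 0

    def test_zero_threshold_gives_complete_graph(self, rng):
        fc = random_fc(rng, 6)
        adj = threshold_adjacency(fc, t=0.0)
        assert np.array_equal(adj.values, 1 - np.eye(6, dtype=np.int8))

    def test_threshold_above_one_gives_empty_graph(self, rng):
        adj = threshold_adjacency(random_fc(rng, 5), t=1.5)
        assert adj.values.sum() == 0


class TestCenters:
    def test_path_graph_top_two_by_degree_then_id(self):
        fc = fc_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        adj = threshold_adjacency(fc, t=0.5)
        assert select_centers(adj) == [1, 2]  # ceil(sqrt(4)) = 2

    def test_star_hub_selected_first(self):
        fc = fc_from_edges(5, [(2, j) for j in (0, 1, 3, 4)])
        adj = threshold_adjacency(fc, t=0.5)
        assert select_centers(adj)[0] == 2

    def test_edgeless_graph_falls_back_to_lowest_ids(self):
        adj = threshold_adjacency(fc_from_edges(9, [], weak=0.0), t=0.5)
        assert select_centers(adj) == [0, 1, 2]  # ceil(sqrt(9)) = 3


class TestAssignment:
    def test_path_with_tied_midpoint_goes_to_earlier_center(self):
        fc = fc_from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        adj = threshold_adjacency(fc, t=0.5)
        subs = assign_to_centers(adj, [0, 4], fc=fc)
        assert subs[0].vertex_ids == (0, 1, 2)  # vertex 2 tied at hop 2
        assert subs[1].vertex_ids == (3, 4)

    def test_all_vertices_as_centers_gives_singletons(self):
        fc = fc_from_edges(4, [(0, 1), (2, 3)])
        adj = threshold_adjacency(fc, t=0.5)
        subs = assign_to_centers(adj, [0, 1, 2, 3], fc=fc)
        assert [s.vertex_ids for s in subs] == [(0,), (1,), (2,), (3,)]

    def test_unreachable_vertex_assigned_by_feature_distance(self):
        # vertex 3 is isolated in the graph; its FC row is close to center 2's
        f = np.full((4, 4), 0.0)
        f[0, 1] = f[1, 0] = 0.9
        f[0, 2] = f[2, 0] = 0.9
        f[2, 3] = f[3, 2] = 0.25  # below threshold but makes rows 2,3 similar
        np.fill_diagonal(f, 1.0)
        fc = FCMatrix(values=f)
        adj = threshold_adjacency(fc, t=0.5)
        subs = assign_to_centers(adj, [0, 2], fc=fc)
        assert 3 in subs[1].vertex_ids

    def test_subnetworks_partition_vertices(self, rng):
        for _ in range(30):
            fc = random_fc(rng, int(rng.integers(5, 15)))
            adj = threshold_adjacency(fc, t=float(rng.uniform(0.1, 0.8)))
            centers = select_centers(adj)
            subs = assign_to_centers(adj, centers, fc=fc)
            all_vs = sorted(v for s in subs for v in s.vertex_ids)
            assert all_vs == list(range(fc.n_rois))


class TestSplitSeeds:
    def test_six_path_selects_degree_two_pair_at_hop_three(self):
        assert choose_split_seeds(path_graph_sub(6)) == (1, 4)

    def test_complete_graph_has_no_qualifying_pair(self):
        n = 5
        edges = frozenset((i, j) for i in range(n) for j in range(i + 1, n))
        sub = Subnetwork(vertex_ids=tuple(range(n)), internal_edges=edges, center=0)
        assert choose_split_seeds(sub) is None

    def test_bridged_triangles_skip_adjacent_hubs(self):
        # triangles {0,1,2} and {3,4,5} bridged by 2-3: the degree-3
        # endpoints are at hop 1, so the best qualifying pair comes from
        # enumerating the remaining hop>2 pairs: degree pair (2,2),
        # smallest ids -> (0, 4)
        edges = frozenset([(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)])
        sub = Subnetwork(vertex_ids=tuple(range(6)), internal_edges=edges, center=0)
        assert choose_split_seeds(sub) == (0, 4)

    def test_disconnected_pair_qualifies(self):
        edges = frozenset([(0, 1), (2, 3)])
        sub = Subnetwork(vertex_ids=(0, 1, 2, 3), internal_edges=edges, center=0)
        assert choose_split_seeds(sub) == (0, 2)

    def test_small_subnetworks_never_split(self):
        assert choose_split_seeds(path_graph_sub(3)) is None


class TestBipartition:
    def test_six_path_splits_at_seeds(self):
        gl, gr = bipartition_bfs(path_graph_sub(6), 1, 4)
        assert gl.vertex_ids == (0, 1, 2)
        assert gr.vertex_ids == (3, 4, 5)
        assert gl.depth == gr.depth == 1

    def test_ties_in_complete_graph_go_to_first_seed(self):
        edges = frozenset((i, j) for i in range(4) for j in range(i + 1, 4))
        sub = Subnetwork(vertex_ids=(0, 1, 2, 3), internal_edges=edges, center=0)
        gl, gr = bipartition_bfs(sub, 0, 3)
        assert gl.vertex_ids == (0, 1, 2)
        assert gr.vertex_ids == (3,)

    def test_two_components_separate_exactly(self):
        edges = frozenset([(0, 1), (1, 2), (3, 4)])
        sub = Subnetwork(vertex_ids=(0, 1, 2, 3, 4), internal_edges=edges, center=0)
        gl, gr = bipartition_bfs(sub, 0, 3)
        assert gl.vertex_ids == (0, 1, 2)
        assert gr.vertex_ids == (3, 4)


class TestAverageDegree:
    @pytest.mark.parametrize(
        "edges,n,expected",
        [
            ([(0, 1), (1, 2), (0, 2)], 3, 2.0),  # triangle
            ([(0, 1), (1, 2)], 3, 4.0 / 3.0),  # path of 3
            ([], 1, 0.0),  # singleton
        ],
    )
    def test_formula(self, edges, n, expected):
        sub = Subnetwork(vertex_ids=tuple(range(n)), internal_edges=frozenset(edges), center=0)
        assert average_degree(sub) == pytest.approx(expected)


class TestRecursivePartition:
    def test_two_cliques_with_bridge_stay_whole(self):
        clique_a = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        clique_b = [(i, j) for i in range(5, 10) for j in range(i + 1, 10)]
        fc = fc_from_edges(10, clique_a + clique_b + [(4, 5)])
        hg, tree = recursive_partition(fc, t=0.5, n_centers=2)
        assert sorted(hg.hyperedges) == [(0, 1, 2, 3, 4), (5, 6, 7, 8, 9)]
        assert all(l.stop_reason == "no_seed_pair" for l in tree.leaves())

    def test_complete_graph_keeps_initial_assignment(self):
        n = 9
        fc = fc_from_edges(n, [(i, j) for i in range(n) for j in range(i + 1, n)])
        hg, tree = recursive_partition(fc, t=0.5)
        leaves = tree.leaves()
        assert all(l.subnetwork.depth == 0 for l in leaves)
        assert sorted(v for e in hg.hyperedges for v in e) == list(range(n))

    def test_tiny_input_gives_single_hyperedge_with_warning(self, rng):
        fc = random_fc(rng, 3)
        with pytest.warns(RuntimeWarning, match="single hyperedge"):
            hg, _ = recursive_partition(fc)
        assert hg.hyperedges == [(0, 1, 2)]

    def test_leaves_partition_vertices_with_bounded_depth(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 25))
            fc = random_fc(rng, n)
            t = float(rng.uniform(0.05, 0.9))
            hg, tree = recursive_partition(fc, t=t)
            assert sorted(v for e in hg.hyperedges for v in e) == list(range(n))
            for leaf in tree.leaves():
                assert leaf.subnetwork.depth <= 4
                assert leaf.stop_reason in ("strength", "size", "depth", "no_seed_pair")

    def test_accepted_splits_strictly_increase_summed_strength(self, rng):
        for _ in range(30):
            fc = random_fc(rng, int(rng.integers(8, 20)))
            _, tree = recursive_partition(fc, t=0.3)

            def walk(node):
                if not node.is_leaf:
                    parent = average_degree(node.subnetwork)
                    child_sum = sum(average_degree(c.subnetwork) for c in node.children)
                    assert child_sum > parent
                    for c in node.children:
                        walk(c)

            for r in tree.roots:
                walk(r)

    def test_deterministic_given_identical_inputs(self, rng):
        fc = random_fc(rng, 15)
        h1, t1 = recursive_partition(fc, t=0.25)
        h2, t2 = recursive_partition(fc, t=0.25)
        assert h1.hyperedges == h2.hyperedges
        assert [l.stop_reason for l in t1.leaves()] == [l.stop_reason for l in t2.leaves()]

    def test_matches_reference_implementation_on_small_graphs(self):
        rng = np.random.default_rng(99)
        for _ in range(60):
            n = int(rng.integers(4, 11))
            fc = random_fc(rng, n)
            t = float(rng.uniform(0.1, 0.8))
            hg, _ = recursive_partition(fc, t=t)
            ref = reference_partition(fc.values, t=t, d_max=4)
            assert hg.hyperedges == ref

    def test_tree_json_export(self, rng, tmp_path):
        fc = random_fc(rng, 12)
        _, tree = recursive_partition(fc, t=0.3)
        tree.to_json(tmp_path / "tree.json")
        import json

        data = json.loads((tmp_path / "tree.json").read_text())
        assert data["d_max"] == 4
        assert len(data["trees"]) == len(tree.roots)


class TestBinaryAdjacency:
    def test_asymmetric_rejected(self):
        v = np.zeros((3, 3), dtype=int)
        v[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            BinaryAdjacency(values=v, threshold_used=0.5)
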