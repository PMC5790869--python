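"""Structural analysis of networks: validation, cut-edges, splits, blobs,
level, and leaf deletion."""

import networkx as nx
import pytest

import treespan as ts
from treespan.network import NetworkError, _norm_edge
from treespan._iso import networks_isomorphic


def brute_force_bridges(N):
    """Remove-and-test-connectivity oracle for cut-edges."""
    out = []
    for e in N.edges:
        G = nx.restricted_view(N.graph, [], [e])
        if not nx.is_connected(G):
            out.append(e)
    return tuple(sorted(out))


class TestValidation:
    def test_single_vertex_network_is_valid(self):
        N = ts.PhyloNetwork.single_vertex("x")
        assert N.leaves == ("x",) and len(N) == 1

    def test_degree_two_vertex_rejected(self):
        with pytest.raises(NetworkError, match="degree"):
            ts.validate_network(nx.Graph([("a", "u"), ("u", "b")]))

    def test_degree_four_vertex_rejected(self):
        G = nx.star_graph(4)
        G = nx.relabel_nodes(G, {i: str(i) for i in G})
        with pytest.raises(NetworkError, match="degree"):
            ts.validate_network(G)

    def test_disconnected_rejected(self):
        G = nx.Graph([("a", "b"), ("c", "d")])
        with pytest.raises(NetworkError, match="connected"):
            ts.validate_network(G)

    def test_loop_and_parallel_rejected(self):
        G = nx.MultiGraph([("a", "b"), ("a", "b")])
        with pytest.raises(NetworkError, match="parallel"):
            ts.validate_network(G)
        G = nx.Graph()
        G.add_edge("a", "a")
        with pytest.raises(NetworkError, match="loop"):
            ts.validate_network(G)

    def test_declared_leaves_must_match(self, quartet):
        with pytest.raises(NetworkError, match="[Dd]eclared"):
            ts.validate_network(quartet.graph, declared_leaves={"a", "b"})

    def test_petersen_derived_network_is_valid(self, petersen_net):
        assert petersen_net.leaf_set == {"x", "y"}
        assert len(petersen_net) == 14
        assert all(petersen_net.degree(v) == 3
                   for v in petersen_net.internal_vertices)


class TestCutEdges:
    def test_every_tree_edge_is_a_bridge(self, quartet):
        assert ts.cut_edges(quartet) == quartet.edges

    def test_petersen_net_bridges_are_the_pendants(self, petersen_net):
        pend = tuple(sorted(
            _norm_edge(l, next(iter(petersen_net.graph[l])))
            for l in petersen_net.leaves))
        assert ts.cut_edges(petersen_net) == pend

    def test_triangle3_bridges_are_the_pendants(self, triangle3):
        assert len(ts.cut_edges(triangle3)) == 3

    def test_agrees_with_remove_and_test_oracle(self, small_fixture_networks):
        for N in small_fixture_networks:
            assert ts.cut_edges(N) == brute_force_bridges(N), N

    def test_trivial_cut_edges(self, quartet, two_blob):
        assert ts.is_trivial_cut_edge(quartet, ("a", "i1"))
        assert not ts.is_trivial_cut_edge(quartet, ("i1", "i2"))
        assert not ts.is_trivial_cut_edge(two_blob, ("a3", "b3"))

    def test_non_cut_edge_rejected(self, triangle3):
        with pytest.raises(NetworkError, match="cut-edge"):
            ts.is_trivial_cut_edge(triangle3, ("u1", "u2"))


class TestSplits:
    def test_quartet_middle_edge_split(self, quartet):
        s = ts.induced_split(quartet, ("i1", "i2"))
        assert {s.side_a, s.side_b} == {frozenset("ab"), frozenset("cd")}

    def test_pendant_edge_split(self, quartet):
        s = ts.induced_split(quartet, ("a", "i1"))
        assert {s.side_a, s.side_b} == {frozenset("a"), frozenset("bcd")}

    def test_single_leaf_network_has_splitless_cut_edge(self, single_leaf_improper):
        (e,) = ts.cut_edges(single_leaf_improper)
        assert ts.induced_split(single_leaf_improper, e) is None
        assert not ts.is_proper(single_leaf_improper)

    def test_trees_and_generated_networks_are_proper(self, quartet):
        assert ts.is_proper(quartet)
        for seed in range(3):
            net, _ = ts.random_tree_based_network(
                list("abcde"), extra_edges=2, seed=seed)
            assert ts.is_proper(net)

    def test_split_consistency_with_properness(self, small_fixture_networks):
        for N in small_fixture_networks:
            all_split = all(ts.induced_split(N, e) is not None
                            for e in ts.cut_edges(N))
            assert all_split == ts.is_proper(N)


class TestBlobs:
    def test_tree_has_no_blobs(self, quartet):
        assert ts.blobs(quartet) == []
        assert ts.strict_level(quartet) == 0

    def test_petersen_net_single_blob_of_twelve(self, petersen_net):
        (B,) = ts.blobs(petersen_net)
        assert len(B.vertices) == 12
        assert B.cycle_rank == 6

    def test_two_blob_network(self, two_blob):
        bs = ts.blobs(two_blob)
        assert len(bs) == 2
        for B in bs:
            BN = ts.blob_network(two_blob, B)
            assert ts.is_simple_network(BN)
            assert len(BN.leaves) == len(B.attachment_edges) >= 2

    def test_single_blob_network_equals_itself(self, petersen_net):
        (B,) = ts.blobs(petersen_net)
        BN = ts.blob_network(petersen_net, B)
        assert networks_isomorphic(BN, petersen_net)

    def test_cycle_rank_sum_identity(self, small_fixture_networks):
        # sum of blob cycle ranks == |E| - |V| + 1 for connected graphs
        for N in small_fixture_networks:
            total = sum(B.cycle_rank for B in ts.blobs(N))
            assert total == N.graph.number_of_edges() - len(N) + 1


class TestLevel:
    def test_known_levels(self, petersen_net, k4_net, triangle3, level2_unique):
        assert ts.strict_level(petersen_net) == 6
        assert ts.strict_level(k4_net) == 3
        assert ts.strict_level(triangle3) == 1
        assert ts.strict_level(level2_unique) == 2

    def test_at_most_semantics(self, triangle3):
        assert ts.is_level(triangle3, 1) and ts.is_level(triangle3, 5)
        assert not ts.is_level(triangle3, 0)

    def test_simple_networks_are_not_big_trees(self, quartet, star3,
                                               petersen_net):
        # trees on more than 3 leaves are not simple networks
        assert not ts.is_simple_network(quartet)
        assert ts.is_simple_network(star3)
        assert ts.is_simple_network(petersen_net)


class TestLeafDeletion:
    def test_quartet_minus_leaf_is_star(self, quartet, star3):
        res = ts.delete_leaf(quartet, "d")
        assert not res.degenerate
        assert res.network.leaf_set == {"a", "b", "c"}
        assert res.network.is_tree and len(res.network) == 4

    def test_single_edge_minus_leaf_is_single_vertex(self):
        N = ts.PhyloTree.from_edges([("x", "y")])
        res = ts.delete_leaf(N, "y")
        assert len(res.network) == 1 and res.network.leaves == ("x",)

    def test_triangle3_deletion_is_degenerate(self, triangle3):
        res = ts.delete_leaf(triangle3, "a")
        assert res.degenerate and res.network is None
        assert "parallel" in res.reason

    def test_petersen_net_minus_leaf_is_single_leaf_network(self, petersen_net):
        res = ts.delete_leaf(petersen_net, "y")
        assert not res.degenerate
        assert res.network.leaves == ("x",)
        assert len(res.network) == 12
        assert not ts.is_proper(res.network)

    def test_errors(self, quartet):
        with pytest.raises(NetworkError):
            ts.delete_leaf(quartet, "i1")
        with pytest.raises(NetworkError):
            ts.delete_leaf(ts.PhyloNetwork.single_vertex("x"), "x")

    def test_delete_then_reattach_recovers_network(self, quartet, petersen_net):
        for N, leaf in ((quartet, "d"), (petersen_net, "y")):
            v = next(iter(N.graph[leaf]))
            a, b = sorted(w for w in N.graph[v] if w != leaf)
            res = ts.delete_leaf(N, leaf)
            back = ts.attach_leaf(res.network, (a, b), leaf)
            assert networks_isomorphic(back, N)
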