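"""Generators and enumeration engines: named graphs, the cubic-graph
reduction, Hamiltonicity, multigraph enumeration, pendant insertion,
random tree-based networks, and the pendant gadget."""

import itertools

import networkx as nx
import pytest

import treespan as ts
from treespan.network import NetworkError
from treespan._iso import networks_isomorphic, tree_canonical


class TestNamedGraphs:
    def test_petersen_structure(self):
        C = ts.petersen()
        assert len(C) == 10 and len(C.edges) == 15
        cycles = nx.minimum_cycle_basis(nx.Graph(C.graph))
        assert min(len(c) for c in cycles) == 5  # girth 5

    def test_k4(self):
        C = ts.complete_graph_k4()
        assert len(C) == 4 and len(C.edges) == 6

    def test_k33_has_a_hamiltonian_cycle(self):
        C = ts.complete_bipartite_k33()
        cycles = ts.hamiltonian_cycles_through(C, C.edges[0], limit=1)
        assert cycles and len(cycles[0]) == 6

    def test_petersen_is_not_hamiltonian(self):
        assert not ts.is_hamiltonian(ts.petersen())

    def test_k4_is_hamiltonian(self):
        assert ts.is_hamiltonian(ts.complete_graph_k4())


class TestCubicToNetwork:
    def test_k4_reduction(self):
        C = ts.complete_graph_k4()
        N = ts.cubic_to_network(C, C.edges[0])
        assert len(N) == 8 and N.leaf_set == {"x", "y"}
        assert ts.strict_level(N) == 3

    def test_petersen_reduction_counts(self):
        C = ts.petersen()
        N = ts.cubic_to_network(C, C.edges[0])
        assert len(N) == 14
        assert ts.strict_level(N) == 6
        assert len(N) == 2 * (2 - 1 + 6)  # |V| = 2(|X| - 1 + k)

    def test_output_is_simple(self):
        for C in (ts.complete_graph_k4(), ts.petersen(),
                  ts.complete_bipartite_k33()):
            for e in C.edges[:3]:
                N = ts.cubic_to_network(C, e)
                assert ts.is_simple_network(N)
                assert ts.is_proper(N)

    def test_non_edge_rejected(self):
        C = ts.complete_bipartite_k33()
        with pytest.raises(NetworkError):
            ts.cubic_to_network(C, ("a1", "a2"))


def burnside_multigraph_count(n):
    """Independent orbit count of connected cubic multigraphs on n labelled
    vertices: enumerate all adjacency assignments, then count orbits of the
    symmetric group directly (Burnside / orbit-stabilizer-free grouping)."""
    verts = list(range(n))
    pairs = list(itertools.combinations(verts, 2))
    graphs = set()
    for loops in itertools.product((0, 1), repeat=n):
        for mults in itertools.product(range(4), repeat=len(pairs)):
            deg = [2 * loops[v] for v in verts]
            for (i, j), m in zip(pairs, mults):
                deg[i] += m
                deg[j] += m
            if any(d != 3 for d in deg):
                continue
            M = nx.MultiGraph()
            M.add_nodes_from(verts)
            for v in verts:
                if loops[v]:
                    M.add_edge(v, v)
            for (i, j), m in zip(pairs, mults):
                for _ in range(m):
                    M.add_edge(i, j)
            if not nx.is_connected(M):
                continue
            graphs.add((loops, mults))
    # group labelled graphs into orbits under vertex permutations
    orbits = 0
    seen = set()
    pair_index = {p: k for k, p in enumerate(pairs)}
    for g in sorted(graphs):
        if g in seen:
            continue
        orbits += 1
        loops, mults = g
        for perm in itertools.permutations(verts):
            ploops = tuple(loops[perm.index(v)] for v in verts)
            pmults = [0] * len(pairs)
            for (i, j), m in zip(pairs, mults):
                a, b = sorted((perm[i], perm[j]))
                pmults[pair_index[(a, b)]] = m
            seen.add((ploops, tuple(pmults)))
    return orbits


class TestMultigraphEnumeration:
    def test_two_vertex_generators(self):
        gs = ts.enumerate_cubic_multigraphs(2)
        # exactly the triple edge and the loop-edge-loop dumbbell
        assert len(gs) == 2
        profiles = sorted(nx.number_of_selfloops(G.multigraph) for G in gs)
        assert profiles == [0, 2]

    def test_four_vertex_count_against_orbit_oracle(self):
        assert len(ts.enumerate_cubic_multigraphs(4)) == \
            burnside_multigraph_count(4)

    def test_outputs_are_connected_cubic(self):
        for G in ts.enumerate_cubic_multigraphs(4):
            M = G.multigraph
            assert nx.is_connected(M)
            assert all(M.degree(v) == 3 for v in M)

    def test_outputs_pairwise_non_isomorphic(self):
        from treespan._iso import multigraphs_isomorphic

        gs = [G.multigraph for G in ts.enumerate_cubic_multigraphs(4)]
        for A, B in itertools.combinations(gs, 2):
            assert not multigraphs_isomorphic(A, B)

    def test_simple_cubic_graph_counts(self):
        # known: 1 connected cubic graph on 4 vertices (K4), 2 on 6
        assert len(ts.enumerate_cubic_graphs(4)) == 1
        assert len(ts.enumerate_cubic_graphs(6)) == 2

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            ts.enumerate_cubic_multigraphs(3)
        with pytest.raises(ValueError):
            ts.enumerate_cubic_multigraphs(10)


class TestNetworksFromGenerator:
    def test_unique_simple_level2_network(self, level2_unique):
        # up to isomorphism there is exactly one simple level-2 network on
        # {x, y}; the session fixture already asserts uniqueness
        assert ts.strict_level(level2_unique) == 2
        assert ts.is_simple_network(level2_unique)
        assert len(level2_unique) == 2 * (2 - 1 + 2)

    def test_loops_need_two_insertions(self):
        # the dumbbell generator (two loops) only yields valid networks
        # when each loop is subdivided at least twice
        dumbbell = next(
            G for G in ts.enumerate_cubic_multigraphs(2)
            if nx.number_of_selfloops(G.multigraph))
        nets = ts.networks_from_generator(dumbbell, ("x", "y"))
        assert nets == []  # two leaves cannot fix two loops and stay simple

    def test_level_equals_generator_cycle_rank(self):
        for G in ts.enumerate_cubic_multigraphs(4):
            for N in ts.networks_from_generator(G, ("x", "y")):
                assert ts.strict_level(N) == G.cycle_rank
                assert ts.is_simple_network(N)

    def test_outputs_deduplicated(self):
        for G in ts.enumerate_cubic_multigraphs(4):
            nets = ts.networks_from_generator(G, ("x", "y"))
            for A, B in itertools.combinations(nets, 2):
                assert not networks_isomorphic(A, B)


class TestRandomTreeBased:
    def test_zero_extra_edges_gives_a_tree(self):
        net, S = ts.random_tree_based_network(list("abcde"), 0, seed=3)
        assert net.is_tree
        assert S.edges == frozenset(net.edges)

    def test_witness_is_a_support_tree(self):
        for seed in range(5):
            net, S = ts.random_tree_based_network(
                list("abcdef"), extra_edges=3, seed=seed)
            T = S.tree_graph()
            assert set(T.nodes()) == set(net.graph.nodes())
            assert nx.is_tree(T)
            assert {v for v in T if T.degree(v) == 1} == net.leaf_set
            assert ts.is_tree_based(net)

    def test_fixed_seed_reproducible(self):
        a, _ = ts.random_tree_based_network(list("abcde"), 2, seed=11)
        b, _ = ts.random_tree_based_network(list("abcde"), 2, seed=11)
        assert a == b

    def test_two_leaves_cannot_take_extra_edges(self):
        with pytest.raises(NetworkError):
            ts.random_tree_based_network(["x", "y"], extra_edges=1, seed=0)


class TestPhyloTreeEnumeration:
    def test_counts_follow_double_factorial(self):
        for n, count in ((1, 1), (2, 1), (3, 1), (4, 3), (5, 15), (6, 105)):
            X = [f"x{i}" for i in range(n)]
            assert len(ts.enumerate_phylo_trees(X)) == count

    def test_trees_pairwise_distinct(self):
        trees = ts.enumerate_phylo_trees(["a", "b", "c", "d", "e"])
        canons = {tree_canonical(T) for T in trees}
        assert len(canons) == len(trees)

    def test_out_of_budget_rejected(self):
        with pytest.raises(ValueError):
            ts.enumerate_phylo_trees([f"x{i}" for i in range(7)])


class TestPendantGadget:
    def test_identity_gadget_is_a_no_op(self, quartet):
        edge_tree = ts.PhyloTree.from_edges([("x", "y")])
        out = ts.replace_pendant_with_gadget(quartet, "a", edge_tree)
        assert networks_isomorphic(out, quartet)

    def test_gadget_graft_keeps_leaf_count(self, level5_net):
        net, _ = ts.random_tree_based_network(list("abcde"), 2, seed=5)
        out = ts.replace_pendant_with_gadget(net, "a", level5_net)
        assert out.leaf_set == net.leaf_set
        assert ts.validate_network(out.graph) is not None

    def test_non_tree_based_gadget_destroys_tree_basedness(self, level5_net):
        net, _ = ts.random_tree_based_network(list("abcde"), 2, seed=5)
        out = ts.replace_pendant_with_gadget(net, "a", level5_net)
        assert not ts.is_tree_based(out)

    def test_strictly_level_k_non_tree_based_networks_exist(self, level5_net):
        # graft the strict level-5 gadget onto tree-based simple networks
        # of strict level 5, 6, 7 (prism reductions): level is unchanged
        for m in (4, 5, 6):
            prism = nx.circular_ladder_graph(m)
            prism = nx.relabel_nodes(prism, {v: f"p{v}" for v in prism})
            C = ts.CubicGraph(prism)
            base = ts.cubic_to_network(C, C.edges[0])
            k = ts.strict_level(base)
            assert k == m + 1
            assert ts.is_tree_based(base)
            out = ts.replace_pendant_with_gadget(base, "x", level5_net)
            assert ts.strict_level(out) == k
            assert not ts.is_tree_based(out)
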