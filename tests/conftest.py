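"""Shared fixtures: small named networks and the enumeration suites.

Everything is generated programmatically; the expensive searches (the
exhaustive strict level-5 hunt, the n=8 cubic-graph list) are session-scoped
so they run once.
"""

import pytest

import treespan as ts


def quartet_tree():
    """Unrooted quartet with cherries {a,b} | {c,d}."""
    return ts.PhyloTree.from_edges(
        [("a", "i1"), ("b", "i1"), ("i1", "i2"), ("i2", "c"), ("i2", "d")]
    )


def star3_tree():
    return ts.PhyloTree.from_edges([("i0", "a"), ("i0", "b"), ("i0", "c")])


def triangle3_network():
    """Triangle with a pendant leaf on each corner: the smallest simple
    level-1 network on three leaves."""
    return ts.PhyloNetwork.from_edges(
        [("u1", "u2"), ("u2", "u3"), ("u1", "u3"),
         ("u1", "a"), ("u2", "b"), ("u3", "c")]
    )


def two_blob_network():
    """Two triangles joined by a bridge, pendant leaves added for validity."""
    return ts.PhyloNetwork.from_edges(
        [("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
         ("b1", "b2"), ("b2", "b3"), ("b1", "b3"),
         ("a3", "b3"),
         ("a1", "l1"), ("a2", "l2"), ("b1", "l3"), ("b2", "l4")]
    )


def subdivided_k4_single_leaf():
    """K4 with one edge subdivided once and a pendant leaf on the new
    vertex: a valid one-leaf network that is not proper."""
    K = ts.complete_graph_k4()
    import networkx as nx

    G = nx.Graph(K.graph)
    a, b = K.edges[0]
    G.remove_edge(a, b)
    G.add_edges_from([(a, "s"), ("s", b), ("s", "x")])
    return ts.PhyloNetwork(G, leaves={"x"})


@pytest.fixture
def quartet():
    return quartet_tree()


@pytest.fixture
def star3():
    return star3_tree()


@pytest.fixture
def triangle3():
    return triangle3_network()


@pytest.fixture
def two_blob():
    return two_blob_network()


@pytest.fixture
def single_leaf_improper():
    return subdivided_k4_single_leaf()


@pytest.fixture(scope="session")
def k4_net():
    K = ts.complete_graph_k4()
    return ts.cubic_to_network(K, K.edges[0])


@pytest.fixture(scope="session")
def petersen_net():
    C = ts.petersen()
    return ts.cubic_to_network(C, C.edges[0])


@pytest.fixture(scope="session")
def level2_unique():
    (G1, G2) = ts.enumerate_cubic_multigraphs(2)
    nets = []
    for G in (G1, G2):
        nets += ts.networks_from_generator(G, ("x", "y"))
    assert len(nets) == 1
    return nets[0]


@pytest.fixture(scope="session")
def level5_net():
    """The exhaustively-found simple strict level-5 non-tree-based network."""
    return ts.find_level5_counterexample()


@pytest.fixture(scope="session")
def simple_nets_by_level():
    """All simple two-leaf networks from generators on 2/4/6 vertices,
    keyed by their strict level (2, 3, 4)."""
    out = {}
    for n in (2, 4, 6):
        nets = []
        for G in ts.enumerate_cubic_multigraphs(n):
            nets += ts.networks_from_generator(G, ("x", "y"))
        out[n // 2 + 1] = nets
    return out


@pytest.fixture
def small_fixture_networks(quartet, star3, triangle3, two_blob,
                           single_leaf_improper, k4_net, petersen_net,
                           level2_unique):
    """Mixed bag of small networks (<= 14 vertices) for oracle agreement."""
    nets = [quartet, star3, triangle3, two_blob, single_leaf_improper,
            k4_net, petersen_net, level2_unique,
            ts.PhyloNetwork.single_vertex("x"),
            ts.PhyloTree.from_edges([("x", "y")])]
    for seed in (1, 2, 3):
        net, _ = ts.random_tree_based_network(
            ["a", "b", "c", "d"], extra_edges=2, seed=seed)
        if len(net) <= 14:
            nets.append(net)
    return nets
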