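"""Isomorphism helpers for small leaf-labelled graphs and multigraphs.

Leaves of a network are distinguishable (they carry taxon labels); internal
vertices are not.  Multigraphs are compared after subdividing every edge
(including loops) with two fresh vertices, which turns parallel edges and
loops into plain simple-graph structure that VF2 and WL hashing understand.
"""

from __future__ import annotations

import networkx as nx
from networkx.algorithms.isomorphism import categorical_node_match


def _leaf_labelled(N):
    """Simple graph with a ``lab`` attribute: taxon name on leaves, None inside."""
    G = nx.Graph()
    X = N.leaf_set
    for v in N.graph.nodes():
        G.add_node(v, lab=(v if v in X else None))
    G.add_edges_from(N.graph.edges())
    return G


def networks_isomorphic(N1, N2):
    """Isomorphism with leaf labels fixed and internal vertices anonymous."""
    if N1.leaf_set != N2.leaf_set:
        return False
    if len(N1) != len(N2) or N1.graph.number_of_edges() != N2.graph.number_of_edges():
        return False
    return nx.is_isomorphic(
        _leaf_labelled(N1), _leaf_labelled(N2),
        node_match=categorical_node_match("lab", None),
    )


def network_hash(N):
    """A leaf-label-aware invariant for bucketing before exact checks."""
    return nx.weisfeiler_lehman_graph_hash(_leaf_labelled(N), node_attr="lab")


def subdivide_multigraph(M):
    """Simple graph encoding of a multigraph: every edge u-v (or loop v-v)
    becomes u-a-b-v with fresh degree-2 vertices a, b; original vertices are
    marked with ``orig=True``."""
    G = nx.Graph()
    for v in M.nodes():
        G.add_node(("o", v), orig=True)
    for i, (u, v) in enumerate(M.edges()):
        a, b = ("s", i, 0), ("s", i, 1)
        G.add_node(a, orig=False)
        G.add_node(b, orig=False)
        G.add_edge(("o", u), a)
        G.add_edge(a, b)
        G.add_edge(b, ("o", v))
    return G


def multigraphs_isomorphic(M1, M2):
    if len(M1) != len(M2) or M1.number_of_edges() != M2.number_of_edges():
        return False
    return nx.is_isomorphic(
        subdivide_multigraph(M1), subdivide_multigraph(M2),
        node_match=categorical_node_match("orig", None),
    )


def multigraph_hash(M):
    return nx.weisfeiler_lehman_graph_hash(subdivide_multigraph(M), node_attr="orig")


def tree_canonical(T):
    """Canonical form of a leaf-labelled tree, leaf labels fixed.

    Rooted at the lexicographically smallest leaf; internal structure
    canonicalized by sorting child forms.  Two trees on the same taxa are
    leaf-preserving isomorphic iff their canonical forms are equal.
    """
    G = T.graph
    if len(G) == 1:
        return ("leaf", next(iter(G.nodes())))
    root = min(T.leaves)
    X = T.leaf_set

    def canon(v, parent):
        children = tuple(sorted(canon(w, v) for w in G.neighbors(v) if w != parent))
        tag = ("leaf", v) if v in X else ("int",)
        return (tag, children)

    return ("rooted", root, canon(root, None))
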