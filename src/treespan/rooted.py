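"""Rooted phylogenetic networks and the orientation correspondence.

An unrooted network N is tree-based iff, for any leaf x, its edges can be
oriented so that removing x and its pendant edge leaves a rooted tree-based
network on X - {x}.  The forward construction is implemented exactly as the
existence argument goes: orient a support tree away from x, then direct every
remaining edge away from whichever endpoint comes first in a topological
order of the tree, which keeps the digraph acyclic.

Rooted tree-basedness (existence of a spanning arborescence whose sinks are
exactly the leaves) is decided by exact search over the in-arc choices at
reticulation vertices: keeping one in-arc per reticulation in a DAG where
every other non-root vertex has indegree 1 automatically yields a spanning
arborescence, so the only thing to verify is that no internal vertex is
stranded as a sink.

Universality (every phylogenetic tree on X is a base-tree) is checked by
enumerating all (2|X|-5)!! trees and testing base-tree containment; a small
bounded randomized search looks for universal networks at desk scale.
"""

from __future__ import annotations

import itertools
import random

import networkx as nx

from .network import NetworkError, PhyloNetwork, _norm_edge
from .recognition import SupportTree, UndecidedError, is_based_on

__all__ = [
    "RootedPhyloNetwork",
    "Orientation",
    "orient_from_support_tree",
    "find_support_arborescence",
    "is_rooted_tree_based",
    "attach_leaf_at_root",
    "is_universal",
    "find_universal_network",
]


class RootedPhyloNetwork:
    """A rooted binary phylogenetic network: a DAG with a single root of
    indegree 0 / outdegree 2, leaves of indegree 1 / outdegree 0, and every
    other vertex of total degree 3 (tree vertices 1-in/2-out, reticulations
    2-in/1-out).  The single-vertex digraph is allowed as a degenerate case
    (its root is also its leaf)."""

    __slots__ = ("_digraph", "_root", "_leaves")

    def __init__(self, digraph, leaves=None):
        D = nx.DiGraph()
        D.add_nodes_from(digraph.nodes())
        D.add_edges_from(digraph.edges())
        if len(D) == 0:
            raise NetworkError("empty digraph is not a rooted network")
        for v in D.nodes():
            if not isinstance(v, str):
                raise NetworkError(f"vertex labels must be strings, got {v!r}")
        if len(D) == 1:
            root = next(iter(D.nodes()))
            X = frozenset([root])
        else:
            if not nx.is_directed_acyclic_graph(D):
                raise NetworkError("digraph has a directed cycle")
            if not nx.is_weakly_connected(D):
                raise NetworkError("digraph is not connected")
            roots = [v for v in D if D.in_degree(v) == 0]
            if len(roots) != 1:
                raise NetworkError(f"expected one root, found {sorted(roots)}")
            root = roots[0]
            if D.out_degree(root) != 2:
                raise NetworkError("root must have outdegree 2")
            X = set()
            for v in D:
                i, o = D.in_degree(v), D.out_degree(v)
                if v == root:
                    continue
                if (i, o) == (1, 0):
                    X.add(v)
                elif (i, o) not in ((1, 2), (2, 1)):
                    raise NetworkError(
                        f"vertex {v!r} has invalid (in, out) degrees ({i}, {o})"
                    )
            if not X:
                raise NetworkError("rooted network has no leaves")
            X = frozenset(X)
        if leaves is not None and frozenset(leaves) != X:
            raise NetworkError("declared leaves differ from sink vertices")
        self._digraph = nx.freeze(D)
        self._root = root
        self._leaves = tuple(sorted(X))

    @property
    def digraph(self):
        return self._digraph

    @property
    def root(self):
        return self._root

    @property
    def leaves(self):
        return self._leaves

    @property
    def leaf_set(self):
        return frozenset(self._leaves)

    @property
    def arcs(self):
        return tuple(sorted(self._digraph.edges()))

    @property
    def reticulations(self):
        """Vertices of indegree 2, sorted."""
        return tuple(
            sorted(v for v in self._digraph if self._digraph.in_degree(v) == 2)
        )

    def __len__(self):
        return len(self._digraph)

    def __eq__(self, other):
        if not isinstance(other, RootedPhyloNetwork):
            return NotImplemented
        return (
            set(self._digraph.nodes()) == set(other._digraph.nodes())
            and set(self._digraph.edges()) == set(other._digraph.edges())
        )

    def __hash__(self):
        return hash(
            (frozenset(self._digraph.nodes()), frozenset(self._digraph.edges()))
        )

    def __repr__(self):
        return (
            f"<RootedPhyloNetwork |V|={len(self)} root={self._root!r} "
            f"X={list(self._leaves)}>"
        )


class Orientation:
    """A total assignment of a direction to every edge of a network."""

    __slots__ = ("_arcs",)

    def __init__(self, arcs):
        self._arcs = {_norm_edge(t, h): (t, h) for t, h in arcs}

    def __getitem__(self, edge):
        return self._arcs[_norm_edge(*edge)]

    def __len__(self):
        return len(self._arcs)

    def __iter__(self):
        return iter(sorted(self._arcs.values()))

    @property
    def arcs(self):
        return tuple(sorted(self._arcs.values()))


def orient_from_support_tree(N, x, S):
    """Orient *N* from support tree *S* away from leaf *x* and root it.

    Tree edges point away from x; vertices are then visited in BFS order
    from x (sorted-neighbor tie-break, a topological order of the oriented
    tree) and every not-yet-oriented edge at the visited vertex is directed
    away from it.  Returns ``(orientation, M)`` where M is the rooted network
    obtained by deleting x and its pendant edge, rooted at x's neighbour.
    """
    if x not in N.leaf_set:
        raise NetworkError(f"{x!r} is not a leaf of N")
    if len(N.leaves) < 2:
        raise NetworkError("orientation requires at least two leaves")
    if not isinstance(S, SupportTree):
        S = SupportTree.of(N, S)
    if S.vertices != frozenset(N.vertices) or not S.edges <= set(N.edges):
        raise NetworkError("S is not a support tree of N")

    T = S.tree_graph()
    order = []
    seen = {x}
    queue = [x]
    arcs = {}
    while queue:
        v = queue.pop(0)
        order.append(v)
        for w in sorted(T.neighbors(v)):
            if w not in seen:
                seen.add(w)
                arcs[_norm_edge(v, w)] = (v, w)
                queue.append(w)
    non_tree = [e for e in N.edges if e not in S.edges]
    pending = set(non_tree)
    for v in order:
        for w in sorted(N.graph.neighbors(v)):
            e = _norm_edge(v, w)
            if e in pending:
                arcs[e] = (v, w)
                pending.remove(e)
    orientation = Orientation(arcs.values())

    (vx,) = list(N.graph.neighbors(x))
    D = nx.DiGraph()
    D.add_nodes_from(v for v in N.vertices if v != x)
    for e, (t, h) in sorted(arcs.items()):
        if x in e:
            continue
        D.add_edge(t, h)
    M = RootedPhyloNetwork(D)
    if M.root != vx:
        raise NetworkError("orientation did not root at the deleted leaf's neighbour")
    return orientation, M


def find_support_arborescence(M, budget=None):
    """A spanning arborescence of *M* whose sinks are exactly the leaves,
    or ``None``.  Exact search over the kept in-arc of each reticulation."""
    D = M.digraph
    if len(D) == 1:
        return frozenset()
    X = M.leaf_set
    retics = M.reticulations
    in_arcs = [tuple(sorted(D.in_edges(r))) for r in retics]
    internal = [v for v in D if v not in X]
    expansions = 0
    for choice in itertools.product(*in_arcs):
        expansions += 1
        if budget is not None and expansions > budget:
            raise UndecidedError("search budget exhausted")
        kept_in = dict(zip(retics, choice))
        ok = True
        for v in internal:
            if not any(
                w not in kept_in or kept_in[w] == (v, w)
                for _, w in D.out_edges(v)
            ):
                ok = False
                break
        if ok:
            dropped = {
                arc
                for r, arcs_r in zip(retics, in_arcs)
                for arc in arcs_r
                if arc != kept_in[r]
            }
            return frozenset(a for a in D.edges() if a not in dropped)
    return None


def is_rooted_tree_based(M, budget=None):
    """True iff *M* contains a spanning arborescence with sink set X."""
    return find_support_arborescence(M, budget=budget) is not None


def attach_leaf_at_root(M, x):
    """Forget directions and hang a new leaf *x* directly on the root.

    The root gains degree 3, so the result is a valid unrooted network on
    leaf_set(M) + {x}; this is the exact inverse of the leaf deletion in the
    orientation correspondence.
    """
    if x in M.digraph:
        raise NetworkError(f"label {x!r} already in use")
    G = nx.Graph()
    G.add_nodes_from(M.digraph.nodes())
    G.add_edges_from(M.digraph.edges())
    G.add_edge(M.root, x)
    return PhyloNetwork(G, leaves=set(M.leaves) | {x})


def is_universal(N, budget=None):
    """Is every phylogenetic tree on X a base-tree of *N*?

    Enumerates all trees on X ((2|X|-5)!! of them) and tests base-tree
    containment for each; practical for |X| <= 5.
    """
    from .constructions import enumerate_phylo_trees

    for T in enumerate_phylo_trees(N.leaves):
        if not is_based_on(N, T, budget=budget):
            return False
    return True


def find_universal_network(X, seed=0, extra_edges=3, max_tries=200, budget=None):
    """Bounded randomized search for a universal network on *X*.

    Draws random tree-based networks (a random tree plus *extra_edges*
    added edges) until one has every tree on X as a base-tree.  Returns the
    network, or ``None`` if *max_tries* is exhausted.
    """
    from .constructions import random_tree_based_network

    rng = random.Random(seed)
    for _ in range(max_tries):
        net, _witness = random_tree_based_network(
            X, extra_edges=extra_edges, seed=rng.randrange(2**31)
        )
        if is_universal(net, budget=budget):
            return net
    return None
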