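"""Exact decision procedures for tree-based networks.

A network is *tree-based* when it has a *support tree*: a spanning tree
whose degree-1 vertices are exactly the taxon set X.  Deciding this is
NP-complete in general, but instances decompose: a network is tree-based iff
the simple network ``B_N`` of every blob is, and every cut-edge belongs to
every support tree.  The solver therefore splits the problem per blob and
runs a depth-first edge-inclusion backtracking search inside each blob,
pruning on degree feasibility (an internal vertex that can no longer reach
tree-degree 2 kills the branch) and on cycle creation (union-find).

On top of the searcher sit: support-tree enumeration, base-tree extraction
(suppress degree-2 vertices), base-tree containment and display checks, and
the fully-tree-based test with both the level-1 characterization and a
definitional subtree-enumeration verifier for cross-validation.

All searches take an optional node-expansion ``budget``; exhausting it
raises :class:`UndecidedError`, never a silent wrong answer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx

from ._iso import tree_canonical
from .network import (
    NetworkError,
    PhyloNetwork,
    PhyloTree,
    _norm_edge,
    blob_network,
    blobs,
    cut_edges,
    is_proper,
    strict_level,
)

__all__ = [
    "UndecidedError",
    "SupportTree",
    "find_support_tree",
    "is_tree_based",
    "iter_support_trees",
    "enumerate_support_trees",
    "base_tree_of",
    "is_based_on",
    "displays",
    "is_fully_tree_based",
    "fully_tree_based_by_definition",
    "find_non_spanning_subtree",
]


class UndecidedError(RuntimeError):
    """The search budget was exhausted before a verdict was reached."""


class _Budget:
    __slots__ = ("remaining",)

    def __init__(self, limit):
        self.remaining = limit

    def tick(self):
        if self.remaining is not None:
            self.remaining -= 1
            if self.remaining < 0:
                raise UndecidedError("search budget exhausted")


@dataclass(frozen=True)
class SupportTree:
    """A spanning tree of a network whose degree-1 vertices are exactly X."""

    vertices: frozenset
    edges: frozenset
    leaves: tuple

    @classmethod
    def of(cls, N, edges):
        """Build and validate a support tree of *N* from an edge collection."""
        edges = frozenset(_norm_edge(u, v) for u, v in edges)
        T = nx.Graph()
        T.add_nodes_from(N.graph.nodes())
        for u, v in edges:
            if not N.graph.has_edge(u, v):
                raise NetworkError(f"({u},{v}) is not an edge of the network")
            T.add_edge(u, v)
        n = len(T)
        if T.number_of_edges() != n - 1 or (n > 1 and not nx.is_connected(T)):
            raise NetworkError("edge set is not a spanning tree")
        if n > 1:
            tree_leaves = {v for v in T if T.degree(v) == 1}
            if tree_leaves != N.leaf_set:
                raise NetworkError(
                    f"tree leaf set {sorted(tree_leaves)} != X {list(N.leaves)}"
                )
        return cls(frozenset(T.nodes()), edges, N.leaves)

    def tree_graph(self):
        T = nx.Graph()
        T.add_nodes_from(self.vertices)
        T.add_edges_from(self.edges)
        return T

    def sorted_edges(self):
        return tuple(sorted(self.edges))


# ---------------------------------------------------------------------------
# Core search: spanning trees of a graph with a prescribed leaf set
# ---------------------------------------------------------------------------

def _iter_constrained_spanning_trees(G, leaf_set, budget):
    """Yield edge-frozensets of spanning trees of *G* whose degree-1 vertices
    are exactly *leaf_set* (every other vertex must have tree-degree >= 2).

    Deterministic: edges are considered in sorted order, inclusion before
    exclusion.  *G* must be connected with at least 2 vertices.
    """
    nodes = sorted(G.nodes())
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    is_leaf = [v in leaf_set for v in nodes]
    edges = sorted(_norm_edge(u, v) for u, v in G.edges())
    m = len(edges)
    eidx = [(idx[u], idx[v]) for u, v in edges]

    deg_chosen = [0] * n
    deg_avail = [G.degree(v) for v in nodes]
    parent = list(range(n))
    rank = [0] * n
    chosen = []

    def find(a):
        while parent[a] != a:
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra == rb:
            return None
        if rank[ra] < rank[rb]:
            ra, rb = rb, ra
        parent[rb] = ra
        if rank[ra] == rank[rb]:
            rank[ra] += 1
        return rb  # the root that was re-parented, for rollback

    def feasible(v):
        if is_leaf[v]:
            return deg_chosen[v] <= 1 and deg_chosen[v] + deg_avail[v] >= 1
        return deg_chosen[v] + deg_avail[v] >= 2

    def rec(i):
        budget.tick()
        if len(chosen) == n - 1:
            for v in range(n):
                if is_leaf[v]:
                    if deg_chosen[v] != 1:
                        return
                elif deg_chosen[v] < 2:
                    return
            yield frozenset(chosen)
            return
        if i == m or len(chosen) + (m - i) < n - 1:
            return
        u, v = eidx[i]
        # include edges[i]
        if not (is_leaf[u] and deg_chosen[u] >= 1) and not (
            is_leaf[v] and deg_chosen[v] >= 1
        ):
            moved = union(u, v)
            if moved is not None:
                deg_chosen[u] += 1
                deg_chosen[v] += 1
                deg_avail[u] -= 1
                deg_avail[v] -= 1
                chosen.append(edges[i])
                yield from rec(i + 1)
                chosen.pop()
                deg_avail[u] += 1
                deg_avail[v] += 1
                deg_chosen[u] -= 1
                deg_chosen[v] -= 1
                parent[moved] = moved
        # exclude edges[i]
        deg_avail[u] -= 1
        deg_avail[v] -= 1
        if feasible(u) and feasible(v):
            yield from rec(i + 1)
        deg_avail[u] += 1
        deg_avail[v] += 1

    yield from rec(0)


# ---------------------------------------------------------------------------
# Support trees via blob-wise decomposition
# ---------------------------------------------------------------------------

def _blob_tree_iters(N, budget):
    """One constrained-search generator per blob (on its simple network B_N)."""
    iters = []
    for B in blobs(N):
        BN = blob_network(N, B)
        iters.append(
            _iter_constrained_spanning_trees(BN.graph, BN.leaf_set, budget)
        )
    return iters


def iter_support_trees(N, budget=None):
    """Lazily yield the support trees of *N* in deterministic order.

    The search runs independently inside each blob and splices the per-blob
    trees together with the cut-edges (which belong to every support tree).
    """
    bud = budget if isinstance(budget, _Budget) else _Budget(budget)
    if len(N) == 1:
        yield SupportTree(frozenset(N.vertices), frozenset(), N.leaves)
        return
    bridges = frozenset(cut_edges(N))
    per_blob = [list(it) for it in _blob_tree_iters(N, bud)]
    if not per_blob:  # N is a tree
        yield SupportTree.of(N, N.edges)
        return
    if any(not options for options in per_blob):
        return
    for combo in itertools.product(*per_blob):
        yield SupportTree.of(N, frozenset().union(bridges, *combo))


def find_support_tree(N, budget=None):
    """A support tree of *N*, or ``None`` if the network is not tree-based."""
    bud = _Budget(budget)
    if len(N) == 1:
        return SupportTree(frozenset(N.vertices), frozenset(), N.leaves)
    bridges = frozenset(cut_edges(N))
    parts = []
    for it in _blob_tree_iters(N, bud):
        first = next(it, None)
        if first is None:
            return None
        parts.append(first)
    return SupportTree.of(N, frozenset().union(bridges, *parts))


def is_tree_based(N, budget=None, use_shortcuts=True):
    """Decide whether *N* has a support tree.

    With ``use_shortcuts`` (default) two sound fast paths apply before any
    search: an improper network is never tree-based, and a proper network of
    strict level at most 4 always is.  ``use_shortcuts=False`` forces the
    pure search, which is what the cross-validation tests exercise.
    """
    if len(N.leaves) == 1:
        return len(N) == 1
    if use_shortcuts:
        if not is_proper(N):
            return False
        if strict_level(N) <= 4:
            return True
    return find_support_tree(N, budget=budget) is not None


def enumerate_support_trees(N, limit=None, budget=None):
    """Distinct support trees of *N*, up to *limit*, deterministic order."""
    it = iter_support_trees(N, budget=budget)
    if limit is not None:
        it = itertools.islice(it, limit)
    return list(it)


# ---------------------------------------------------------------------------
# Base trees, containment, display
# ---------------------------------------------------------------------------

def _suppress_degree_two(T):
    """Suppress every degree-2 vertex of tree graph *T* (returns a copy)."""
    G = nx.Graph(T)
    changed = True
    while changed:
        changed = False
        for v in list(G.nodes()):
            if G.degree(v) == 2:
                a, b = G.neighbors(v)
                G.remove_node(v)
                G.add_edge(a, b)  # cannot already exist in a tree
                changed = True
    return G


def base_tree_of(N, S):
    """The base-tree: suppress all degree-2 vertices of support tree *S*."""
    if not isinstance(S, SupportTree):
        S = SupportTree.of(N, S)
    if S.vertices != frozenset(N.vertices) or not S.edges <= set(N.edges):
        raise NetworkError("S is not a support tree of N")
    if len(S.vertices) == 1:
        return PhyloTree(_single_node_graph(next(iter(S.vertices))))
    return PhyloTree(_suppress_degree_two(S.tree_graph()))


def _single_node_graph(v):
    G = nx.Graph()
    G.add_node(v)
    return G


def is_based_on(N, T, budget=None):
    """Is the phylogenetic tree *T* a base-tree of *N*?

    True iff some support tree of *N* suppresses to a tree isomorphic to *T*
    with leaf labels fixed.  Exact (exponential) search.
    """
    if N.leaf_set != T.leaf_set:
        raise NetworkError("N and T must share the same leaf set")
    target = tree_canonical(T)
    for S in iter_support_trees(N, budget=budget):
        if tree_canonical(base_tree_of(N, S)) == target:
            return True
    return False


def _iter_subtrees_with_leafset(N, budget, proper_only=False):
    """Yield (vertex_set, edge_frozenset) for every subtree of *N* whose
    degree-1 vertices are exactly X.  ``proper_only`` skips spanning ones."""
    bud = budget if isinstance(budget, _Budget) else _Budget(budget)
    X = N.leaf_set
    internal = sorted(N.internal_vertices)
    for size in range(len(internal) + (0 if proper_only else 1)):
        for W in itertools.combinations(internal, size):
            nodes = X | set(W)
            H = N.graph.subgraph(nodes)
            if len(nodes) > 1 and not nx.is_connected(H):
                continue
            if len(nodes) == 1:
                yield frozenset(nodes), frozenset()
                continue
            for edge_set in _iter_constrained_spanning_trees(H, X, bud):
                yield frozenset(nodes), edge_set


def displays(N, T, budget=None):
    """Is *T* displayed by *N*?

    True iff some subtree of *N* (not necessarily spanning) with leaf set X
    suppresses to a tree isomorphic to *T* with leaf labels fixed.
    """
    if N.leaf_set != T.leaf_set:
        raise NetworkError("N and T must share the same leaf set")
    target = tree_canonical(T)
    for nodes, edge_set in _iter_subtrees_with_leafset(N, budget):
        if len(nodes) == 1:
            sub = PhyloTree(_single_node_graph(next(iter(nodes))))
        else:
            G = nx.Graph()
            G.add_nodes_from(nodes)
            G.add_edges_from(edge_set)
            sub = PhyloTree(_suppress_degree_two(G))
        if tree_canonical(sub) == target:
            return True
    return False


def is_fully_tree_based(N):
    """Level-1 characterization: every subtree with leaf set X is a support
    tree iff the network is level-1 (each blob has cycle rank <= 1)."""
    return strict_level(N) <= 1


def find_non_spanning_subtree(N, budget=None):
    """A witness subtree with leaf set X that does **not** span N, or None.

    Used by the definitional fully-tree-based verifier; the first witness in
    deterministic order is returned as (vertex_set, edge_set).
    """
    if len(N) == 1:
        return None
    for nodes, edge_set in _iter_subtrees_with_leafset(N, budget, proper_only=True):
        return frozenset(nodes), frozenset(edge_set)
    return None


def fully_tree_based_by_definition(N, budget=None):
    """Direct verifier of the definition, by exhaustive subtree enumeration.

    Returns ``(verdict, witness)``: the verdict is True iff every subtree of
    N with leaf set X spans N (and hence is a support tree); the witness is a
    non-spanning subtree when the verdict is False.  Exponential in the
    number of internal vertices; meant for small networks and for
    cross-validating :func:`is_fully_tree_based`.
    """
    witness = find_non_spanning_subtree(N, budget=budget)
    if witness is not None:
        return False, witness
    return True, None
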