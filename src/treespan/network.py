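"""Core data model for unrooted phylogenetic networks.

An unrooted phylogenetic network on a taxon set ``X`` is a connected simple
graph in which every vertex has degree 1 or 3 and whose degree-1 vertices are
exactly ``X``.  A phylogenetic tree is such a network whose underlying graph
is a tree.  This module provides the validated container types plus the
structural analyses everything else is built on: cut-edges (bridges) and the
splits they induce, properness, the blob decomposition, the induced simple
network ``B_N`` of a blob, the level of a network, and leaf deletion.

Degenerate cases are first-class: the single-vertex graph on ``{x}`` is a
valid network (the only tree-based network with one leaf), and the single
edge is the valid two-leaf tree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "NetworkError",
    "PhyloNetwork",
    "PhyloTree",
    "Split",
    "Blob",
    "LeafDeletionResult",
    "validate_network",
    "cut_edges",
    "is_trivial_cut_edge",
    "induced_split",
    "is_proper",
    "blobs",
    "blob_network",
    "is_simple_network",
    "strict_level",
    "is_level",
    "delete_leaf",
    "attach_leaf",
    "fresh_label",
]


class NetworkError(ValueError):
    """A graph violates the phylogenetic-network invariants."""


def _norm_edge(u, v):
    return (u, v) if u <= v else (v, u)


def fresh_label(taken, stem="v"):
    """Return a label of the form ``stem#`` not present in *taken*."""
    i = 0
    while f"{stem}{i}" in taken:
        i += 1
    return f"{stem}{i}"


def _check_simple(graph):
    if nx.number_of_selfloops(graph):
        raise NetworkError("graph contains a loop")
    if graph.is_multigraph():
        seen = set()
        for u, v in graph.edges():
            e = _norm_edge(u, v)
            if e in seen:
                raise NetworkError("graph contains parallel edges")
            seen.add(e)


class PhyloNetwork:
    """An unrooted binary phylogenetic network.

    Parameters
    ----------
    graph:
        Anything :class:`networkx.Graph` accepts (a graph or an edge
        iterable).  Vertex labels must be strings.
    leaves:
        Optional declared leaf set; if given it must equal the set of
        degree-1 vertices.
    """

    __slots__ = ("_graph", "_leaves")

    def __init__(self, graph, leaves=None):
        if isinstance(graph, nx.Graph):
            _check_simple(graph)
            G = nx.Graph()
            G.add_nodes_from(graph.nodes())
            G.add_edges_from(graph.edges())
        else:
            G = nx.Graph()
            G.add_edges_from(graph)
        if nx.number_of_selfloops(G):
            raise NetworkError("graph contains a loop")
        if len(G) == 0:
            raise NetworkError("empty graph is not a network")
        for v in G.nodes():
            if not isinstance(v, str):
                raise NetworkError(f"vertex labels must be strings, got {v!r}")
        if not nx.is_connected(G):
            raise NetworkError("graph is not connected")
        if len(G) == 1:
            X = frozenset(G.nodes())
        else:
            bad = [v for v in G if G.degree(v) not in (1, 3)]
            if bad:
                raise NetworkError(
                    f"vertices with degree not in {{1, 3}}: {sorted(bad)}"
                )
            X = frozenset(v for v in G if G.degree(v) == 1)
            if not X:
                raise NetworkError("network has no leaves")
        if leaves is not None and frozenset(leaves) != X:
            raise NetworkError(
                f"declared leaves {sorted(leaves)} != degree-1 vertices {sorted(X)}"
            )
        self._graph = nx.freeze(G)
        self._leaves = tuple(sorted(X))

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_edges(cls, edges, isolated=()):
        G = nx.Graph()
        G.add_nodes_from(isolated)
        G.add_edges_from(edges)
        return cls(G)

    @classmethod
    def single_vertex(cls, label):
        G = nx.Graph()
        G.add_node(label)
        return cls(G)

    # -- basic accessors ------------------------------------------------------

    @property
    def graph(self):
        """The (frozen) underlying :class:`networkx.Graph`."""
        return self._graph

    @property
    def leaves(self):
        """The taxon set X as a sorted tuple."""
        return self._leaves

    @property
    def leaf_set(self):
        return frozenset(self._leaves)

    @property
    def vertices(self):
        return tuple(sorted(self._graph.nodes()))

    @property
    def edges(self):
        return tuple(sorted(_norm_edge(u, v) for u, v in self._graph.edges()))

    @property
    def internal_vertices(self):
        X = self.leaf_set
        return tuple(v for v in self.vertices if v not in X)

    @property
    def is_tree(self):
        return self._graph.number_of_edges() == len(self._graph) - 1

    def degree(self, v):
        return self._graph.degree(v)

    def __len__(self):
        return len(self._graph)

    def __eq__(self, other):
        if not isinstance(other, PhyloNetwork):
            return NotImplemented
        return (
            set(self._graph.nodes()) == set(other._graph.nodes())
            and set(map(frozenset, self._graph.edges()))
            == set(map(frozenset, other._graph.edges()))
        )

    def __hash__(self):
        return hash((frozenset(self._graph.nodes()),
                     frozenset(map(frozenset, self._graph.edges()))))

    def __repr__(self):
        return (
            f"<{type(self).__name__} |V|={len(self)} "
            f"|E|={self._graph.number_of_edges()} X={list(self.leaves)}>"
        )


class PhyloTree(PhyloNetwork):
    """A phylogenetic tree: a network whose underlying graph is a tree."""

    __slots__ = ()

    def __init__(self, graph, leaves=None):
        super().__init__(graph, leaves)
        if not self.is_tree:
            raise NetworkError("graph is not a tree")


@dataclass(frozen=True)
class Split:
    """A bipartition of the taxon set X into two non-empty parts.

    Sides are stored canonically: ``side_a`` contains the smallest label.
    """

    side_a: frozenset
    side_b: frozenset

    def __post_init__(self):
        a, b = frozenset(self.side_a), frozenset(self.side_b)
        if not a or not b:
            raise NetworkError("both sides of a split must be non-empty")
        if a & b:
            raise NetworkError("split sides must be disjoint")
        if min(b) < min(a):
            a, b = b, a
        object.__setattr__(self, "side_a", a)
        object.__setattr__(self, "side_b", b)

    @property
    def taxa(self):
        return self.side_a | self.side_b

    def __str__(self):
        fmt = lambda s: ",".join(sorted(s))
        return f"{fmt(self.side_a)}|{fmt(self.side_b)}"


@dataclass(frozen=True)
class Blob:
    """A maximal cut-edge-free subgraph with more than one vertex."""

    vertices: frozenset
    edges: frozenset  # normalized vertex pairs inside the blob
    attachment_edges: tuple  # cut-edges of N with exactly one endpoint inside

    @property
    def cycle_rank(self):
        return len(self.edges) - len(self.vertices) + 1


def validate_network(graph, declared_leaves=None):
    """Validate *graph* as a phylogenetic network and wrap it.

    Raises :class:`NetworkError` for disconnected graphs, loops or parallel
    edges, vertices of degree 0 (other than the single-vertex network), 2 or
    >= 4, and for a declared leaf set differing from the degree-1 vertices.
    """
    return PhyloNetwork(graph, leaves=declared_leaves)


def cut_edges(N):
    """All bridges of the network, as a sorted tuple of normalized edges."""
    return tuple(sorted(_norm_edge(u, v) for u, v in nx.bridges(N.graph)))


def _require_cut_edge(N, e):
    e = _norm_edge(*e)
    if e not in set(cut_edges(N)):
        raise NetworkError(f"{e} is not a cut-edge")
    return e


def is_trivial_cut_edge(N, e):
    """True iff one side of deleting the cut-edge *e* is a single vertex."""
    e = _require_cut_edge(N, e)
    G = nx.restricted_view(N.graph, [], [e])
    sides = [len(c) for c in nx.connected_components(G)]
    return min(sides) == 1


def induced_split(N, e):
    """The split of X induced by deleting cut-edge *e*, or ``None``.

    Returns ``None`` when one of the two components contains no taxon, which
    is exactly the situation that makes a network improper.
    """
    e = _require_cut_edge(N, e)
    G = nx.restricted_view(N.graph, [], [e])
    comp_a, comp_b = list(nx.connected_components(G))
    X = N.leaf_set
    a, b = X & comp_a, X & comp_b
    if not a or not b:
        return None
    return Split(a, b)


def is_proper(N):
    """True iff every cut-edge of *N* induces a split of X."""
    return all(induced_split(N, e) is not None for e in cut_edges(N))


def blobs(N):
    """The blobs of *N* in deterministic (sorted) order.

    A blob is a non-singleton 2-edge-connected component: a maximal subgraph
    without cut-edges that is not a single vertex.
    """
    bridges = set(cut_edges(N))
    G = nx.restricted_view(N.graph, [], bridges)
    out = []
    for comp in nx.connected_components(G):
        if len(comp) < 2:
            continue
        comp = frozenset(comp)
        inner = frozenset(
            _norm_edge(u, v) for u, v in N.graph.edges(comp) if u in comp and v in comp
        )
        attach = tuple(sorted(e for e in bridges if (e[0] in comp) != (e[1] in comp)))
        out.append(Blob(comp, inner, attach))
    out.sort(key=lambda b: sorted(b.vertices))
    return out


def blob_network(N, B):
    """The simple network ``B_N``: the blob plus its attachment cut-edges.

    The leaves of ``B_N`` are the outer endpoints of the attachment edges
    (vertices of N that may well be internal in N itself).
    """
    return PhyloNetwork.from_edges(sorted(B.edges) + list(B.attachment_edges))


def is_simple_network(N):
    """True iff every cut-edge of *N* is trivial (pendant)."""
    return all(is_trivial_cut_edge(N, e) for e in cut_edges(N))


def strict_level(N):
    """The exact level: the maximum cycle rank over the blobs (0 for trees)."""
    bs = blobs(N)
    return max((b.cycle_rank for b in bs), default=0)


def is_level(N, k):
    """True iff *N* is a level-*k* network (at-most semantics)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return strict_level(N) <= k


@dataclass(frozen=True)
class LeafDeletionResult:
    """Outcome of deleting a leaf; degenerate when suppression would create
    a parallel edge, so the result is not a valid (simple) network."""

    network: PhyloNetwork | None
    degenerate: bool = False
    reason: str | None = None


def delete_leaf(N, x):
    """Delete leaf *x*, suppress the resulting degree-2 vertex.

    Returns a :class:`LeafDeletionResult`; ``degenerate`` is set when the
    suppression would create a parallel edge (e.g. a triangle with pendant
    leaves), in which case no network is returned.
    """
    if x not in N.leaf_set:
        raise NetworkError(f"{x!r} is not a leaf")
    if len(N.leaves) < 2:
        raise NetworkError("cannot delete the leaf of a single-leaf network")
    G = nx.Graph(N.graph)
    (v,) = list(G.neighbors(x))
    G.remove_node(x)
    if G.degree(v) == 0:  # N was the single edge {x, v}
        return LeafDeletionResult(PhyloNetwork.single_vertex(v))
    a, b = sorted(G.neighbors(v))
    if G.has_edge(a, b):
        return LeafDeletionResult(
            None, degenerate=True,
            reason=f"suppressing {v} would create a parallel edge {{{a},{b}}}",
        )
    G.remove_node(v)
    G.add_edge(a, b)
    return LeafDeletionResult(PhyloNetwork(G))


def attach_leaf(N, e, leaf, attach_label=None):
    """Subdivide edge *e* with a new vertex and hang leaf *leaf* from it.

    The inverse of :func:`delete_leaf` (when that was non-degenerate).
    """
    u, v = e
    if not N.graph.has_edge(u, v):
        raise NetworkError(f"{e} is not an edge")
    if leaf in N.graph:
        raise NetworkError(f"label {leaf!r} already in use")
    taken = set(N.graph) | {leaf}
    w = attach_label if attach_label is not None else fresh_label(taken)
    if w in N.graph:
        raise NetworkError(f"label {w!r} already in use")
    G = nx.Graph(N.graph)
    G.remove_edge(u, v)
    G.add_edges_from([(u, w), (w, v), (w, leaf)])
    return PhyloNetwork(G)
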