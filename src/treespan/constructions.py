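"""Generators, reductions and enumeration engines.

This module houses the computational side of the theory:

* the ``C_e(x,y)`` reduction that turns Hamiltonicity of a cubic graph into
  tree-basedness of a two-leaf network (subdivide an edge twice, hang the
  leaves x and y on the subdivision points);
* exact Hamiltonian-cycle search for small cubic graphs, plus the named
  graphs (Petersen via the Kneser (5,2) construction, K4, K3,3);
* isomorph-free enumeration of connected cubic multigraphs on n vertices
  (loops and parallel edges allowed) — the generator multigraphs whose
  pendant-leaf insertions produce exactly the simple level-k networks with
  k = n/2 + 1;
* insertion of pendant leaves into a generator multigraph, yielding all
  simple networks on a given leaf set up to leaf-preserving isomorphism;
* random tree-based networks (a uniform random tree plus edges added
  between subdivision points of the growing support tree), returned with
  their support-tree witness;
* enumeration of all unrooted binary trees on X (1, 1, 1, 3, 15, 105 for
  |X| = 1..6);
* the exhaustive search for a smallest-level non-tree-based simple network
  (strict level 5, 12 vertices) and the pendant-replacement gadget that
  propagates it to every strict level >= 5.
"""

from __future__ import annotations

import functools
import itertools
import random

import networkx as nx

from ._iso import network_hash, networks_isomorphic
from .network import (
    NetworkError,
    PhyloNetwork,
    PhyloTree,
    _norm_edge,
    fresh_label,
    is_simple_network,
    strict_level,
)
from .recognition import SupportTree, UndecidedError, is_tree_based

__all__ = [
    "CubicGraph",
    "CubicMultigraph",
    "petersen",
    "complete_graph_k4",
    "complete_bipartite_k33",
    "cubic_to_network",
    "is_hamiltonian",
    "hamiltonian_cycles_through",
    "enumerate_cubic_multigraphs",
    "iter_cubic_multigraphs",
    "enumerate_cubic_graphs",
    "networks_from_generator",
    "random_tree_based_network",
    "enumerate_phylo_trees",
    "find_level5_counterexample",
    "replace_pendant_with_gadget",
]


class CubicGraph:
    """A connected simple graph in which every vertex has degree 3."""

    __slots__ = ("_graph",)

    def __init__(self, graph):
        G = nx.Graph()
        G.add_nodes_from(graph.nodes() if isinstance(graph, nx.Graph) else ())
        G.add_edges_from(graph.edges() if isinstance(graph, nx.Graph) else graph)
        if nx.number_of_selfloops(G):
            raise NetworkError("cubic graph must be simple (loop found)")
        if len(G) == 0 or not nx.is_connected(G):
            raise NetworkError("cubic graph must be connected and non-empty")
        bad = [v for v in G if G.degree(v) != 3]
        if bad:
            raise NetworkError(f"vertices of degree != 3: {sorted(bad)[:5]}")
        assert 2 * G.number_of_edges() == 3 * len(G)
        self._graph = nx.freeze(G)

    @property
    def graph(self):
        return self._graph

    @property
    def vertices(self):
        return tuple(sorted(self._graph.nodes()))

    @property
    def edges(self):
        return tuple(sorted(_norm_edge(u, v) for u, v in self._graph.edges()))

    def __len__(self):
        return len(self._graph)


class CubicMultigraph:
    """A connected multigraph, loops and parallel edges allowed, in which
    every vertex has degree 3 (a loop contributes 2)."""

    __slots__ = ("_graph",)

    def __init__(self, multigraph):
        M = nx.MultiGraph()
        if isinstance(multigraph, nx.Graph):
            M.add_nodes_from(multigraph.nodes())
            M.add_edges_from(multigraph.edges())
        else:
            M.add_edges_from(multigraph)
        if len(M) == 0 or not nx.is_connected(M):
            raise NetworkError("cubic multigraph must be connected and non-empty")
        bad = [v for v in M if M.degree(v) != 3]
        if bad:
            raise NetworkError(f"vertices of degree != 3: {sorted(bad)[:5]}")
        self._graph = nx.freeze(M)

    @property
    def multigraph(self):
        return self._graph

    @property
    def vertices(self):
        return tuple(sorted(self._graph.nodes()))

    @property
    def edge_list(self):
        return tuple(sorted(_norm_edge(u, v) for u, v, _ in self._graph.edges(keys=True)))

    @property
    def cycle_rank(self):
        return self._graph.number_of_edges() - len(self._graph) + 1

    def __len__(self):
        return len(self._graph)


# ---------------------------------------------------------------------------
# Named graphs
# ---------------------------------------------------------------------------

def petersen():
    """The Petersen graph, via the Kneser (5,2) construction: vertices are
    the 2-subsets of {1..5}, adjacent iff disjoint.  10 vertices, 15 edges,
    girth 5, 3-edge-connected, famously non-Hamiltonian."""
    pairs = list(itertools.combinations("12345", 2))
    G = nx.Graph()
    for a, b in itertools.combinations(pairs, 2):
        if not set(a) & set(b):
            G.add_edge("".join(a), "".join(b))
    return CubicGraph(G)


def complete_graph_k4():
    """K4: the smallest simple cubic graph."""
    G = nx.complete_graph(["a", "b", "c", "d"])
    return CubicGraph(G)


def complete_bipartite_k33():
    G = nx.complete_bipartite_graph(3, 3)
    G = nx.relabel_nodes(G, {0: "a1", 1: "a2", 2: "a3", 3: "b1", 4: "b2", 5: "b3"})
    return CubicGraph(G)


# ---------------------------------------------------------------------------
# The C_e(x, y) reduction
# ---------------------------------------------------------------------------

def cubic_to_network(C, e, x="x", y="y"):
    """Subdivide edge *e* of cubic graph *C* twice and attach leaves x, y.

    The result C_e(x,y) is a network on {x, y}; for a 3-edge-connected C it
    is simple with strict level |E(C)| - |V(C)| + 1 (cycle rank preserved
    under subdivision).
    """
    a, b = e
    if not C.graph.has_edge(a, b):
        raise NetworkError(f"{e} is not an edge of the cubic graph")
    taken = set(C.graph) | {x, y}
    u = fresh_label(taken, "u")
    taken.add(u)
    v = fresh_label(taken, "u")
    G = nx.Graph(C.graph)
    G.remove_edge(a, b)
    G.add_edges_from([(a, u), (u, v), (v, b), (u, x), (v, y)])
    return PhyloNetwork(G, leaves={x, y})


# ---------------------------------------------------------------------------
# Hamiltonicity (exact backtracking)
# ---------------------------------------------------------------------------

def _ham_cycles(G, start_edge=None, limit=None, budget=None):
    nodes = sorted(G.nodes())
    n = len(nodes)
    found = []
    expansions = [0]

    def tick():
        expansions[0] += 1
        if budget is not None and expansions[0] > budget:
            raise UndecidedError("search budget exhausted")

    if start_edge is not None:
        s, t = start_edge
        if not G.has_edge(s, t):
            raise NetworkError(f"{start_edge} is not an edge")
        anchors = [(s, t)]
    else:
        s = nodes[0]
        anchors = [(s, w) for w in sorted(G.neighbors(s))]

    for s0, first in anchors:
        path = [s0, first]
        visited = {s0, first}

        def extend(v):
            tick()
            if len(path) == n:
                if G.has_edge(v, s0):
                    cyc = tuple(path)
                    if start_edge is not None or cyc[1] < cyc[-1]:  # kill reversal dup
                        found.append(cyc)
                return bool(limit and len(found) >= limit)
            for w in sorted(G.neighbors(v)):
                if w not in visited:
                    visited.add(w)
                    path.append(w)
                    if extend(w):
                        return True
                    path.pop()
                    visited.remove(w)
            return False

        if extend(first):
            break
    return found


def is_hamiltonian(C, budget=None):
    """Exact Hamiltonian-cycle test for a (small) cubic graph."""
    return bool(_ham_cycles(C.graph, limit=1, budget=budget))


def hamiltonian_cycles_through(C, e, limit=None, budget=None):
    """Hamiltonian cycles of *C* traversing edge *e*, as vertex tuples."""
    return _ham_cycles(C.graph, start_edge=tuple(e), limit=limit, budget=budget)


# ---------------------------------------------------------------------------
# Cubic multigraph enumeration
# ---------------------------------------------------------------------------

def _labelled_cubic_multigraphs(n, allow_multi=True, allow_loops=True):
    """Yield connected labelled degree-3 multigraphs on vertices 0..n-1 as
    ``(loops, pairs)`` with *loops* the number of looped prefix vertices and
    *pairs* a tuple of ``(i, j, multiplicity)``.

    Loops (when allowed) are restricted to a prefix of the vertex set: every
    isomorphism class has such a representative, so downstream dedup is
    unaffected while the labelled stream shrinks considerably.
    """
    max_mult = 3 if allow_multi else 1
    loop_counts = range(n + 1) if allow_loops else (0,)
    for L in loop_counts:
        rem = [1] * L + [3] * (n - L)
        pair_edges = []

        def place(i, j):
            # distribute rem[i] over partners j..n-1
            if rem[i] == 0:
                yield from assign(i + 1)
                return
            if j == n:
                return
            cap = min(rem[i], rem[j], max_mult)
            for k in range(cap, -1, -1):
                rem[i] -= k
                rem[j] -= k
                if k:
                    pair_edges.append((i, j, k))
                yield from place(i, j + 1)
                if k:
                    pair_edges.pop()
                rem[i] += k
                rem[j] += k

        def assign(i):
            if i == n:
                yield tuple(pair_edges)
                return
            yield from place(i, i + 1)

        for pairs in assign(0):
            # connectivity via union-find on the pair edges (loops irrelevant)
            parent = list(range(n))

            def find(a):
                while parent[a] != a:
                    parent[a] = parent[parent[a]]
                    a = parent[a]
                return a

            comps = n
            for i, j, _k in pairs:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
                    comps -= 1
            if comps == 1 or n == 1:
                yield L, pairs


def _mg_struct(n, loops, pairs):
    """Adjacency structure: (loop flags, neighbor multiplicity dicts)."""
    loop = [1 if v < loops else 0 for v in range(n)]
    nb = [dict() for _ in range(n)]
    for i, j, k in pairs:
        nb[i][j] = k
        nb[j][i] = k
    return loop, nb


def _mg_cert(n, loop, nb):
    """Color-refinement certificate of a degree-3 multigraph (invariant
    under relabelling; used only to bucket before exact checks).

    Returns ``(certificate, colors)``; the per-vertex colors also constrain
    the candidate sets of the exact isomorphism backtracking."""
    colors = _refine_colors(n, loop, nb)
    edge_profile = tuple(sorted(
        (min(colors[i], colors[j]), max(colors[i], colors[j]), k)
        for i, j, k in ((i, j, nb[i][j]) for i in range(n) for j in nb[i] if i < j)
    ))
    cert = (tuple(sorted(zip(colors, loop))), edge_profile)
    return cert, colors


def _mg_isomorphic(n, a, b):
    """Exact multigraph isomorphism by class-constrained backtracking.

    *a*, *b* are ``(loop, nb, colors)`` triples with refinement colors from
    :func:`_mg_cert`-style refinement; certificates are assumed equal."""
    loop1, nb1, col1 = a
    loop2, nb2, col2 = b
    cand = {v: [w for w in range(n) if col2[w] == col1[v] and loop2[w] == loop1[v]]
            for v in range(n)}
    order = sorted(range(n), key=lambda v: (len(cand[v]), v))
    mapping = [-1] * n
    used = [False] * n

    def rec(k):
        if k == n:
            return True
        v = order[k]
        for w in cand[v]:
            if used[w]:
                continue
            ok = True
            for u, m in nb1[v].items():
                mu = mapping[u]
                if mu >= 0 and nb2[w].get(mu) != m:
                    ok = False
                    break
            if ok and len(nb1[v]) == len(nb2[w]):
                mapping[v] = w
                used[w] = True
                if rec(k + 1):
                    return True
                mapping[v] = -1
                used[w] = False
        return False

    return rec(0)


def _refine_colors(n, loop, nb):
    colors = [(loop[v], tuple(sorted(nb[v].values()))) for v in range(n)]
    for _ in range(3):
        sigs = [
            (colors[v], tuple(sorted((m, colors[w]) for w, m in nb[v].items())))
            for v in range(n)
        ]
        relab = {s: c for c, s in enumerate(sorted(set(sigs)))}
        colors = [relab[s] for s in sigs]
    return colors


def iter_cubic_multigraphs(n, allow_multi=True, allow_loops=True):
    """Lazily yield connected cubic multigraphs on *n* vertices, one per
    isomorphism class, in first-seen (deterministic) order."""
    if n % 2 or n < 2:
        raise ValueError("n must be even and >= 2")
    if n > 8:
        raise ValueError("enumeration is supported for n <= 8")
    buckets = {}
    for loops, pairs in _labelled_cubic_multigraphs(n, allow_multi, allow_loops):
        loop, nb = _mg_struct(n, loops, pairs)
        cert, colors = _mg_cert(n, loop, nb)
        reps = buckets.setdefault(cert, [])
        if any(_mg_isomorphic(n, (loop, nb, colors), R) for R in reps):
            continue
        reps.append((loop, nb, colors))
        M = nx.MultiGraph()
        M.add_nodes_from(range(n))
        for v in range(loops):
            M.add_edge(v, v)
        for i, j, k in pairs:
            for _ in range(k):
                M.add_edge(i, j)
        yield CubicMultigraph(M)


def enumerate_cubic_multigraphs(n):
    """All connected cubic multigraphs on *n* vertices up to isomorphism
    (loops and parallel edges allowed), deterministic order."""
    return list(iter_cubic_multigraphs(n))


def enumerate_cubic_graphs(n):
    """All connected *simple* cubic graphs on n vertices up to isomorphism."""
    out = []
    for M in iter_cubic_multigraphs(n, allow_multi=False, allow_loops=False):
        G = nx.relabel_nodes(nx.Graph(M.multigraph), {v: f"c{v}" for v in M.vertices})
        out.append(CubicGraph(G))
    return out


# ---------------------------------------------------------------------------
# Pendant insertion: generator multigraph -> simple networks
# ---------------------------------------------------------------------------

def networks_from_generator(G, leaves):
    """All simple networks on *leaves* obtained by inserting pendant edges
    into the generator multigraph *G*, up to leaf-preserving isomorphism.

    Each insertion subdivides one (multi)edge with a fresh attachment vertex
    carrying the pendant leaf; several insertions may land on the same edge.
    Placements that leave a loop or parallel pair (e.g. a loop receiving
    fewer than two insertions) or a non-trivial cut-edge are discarded, so
    every output is a valid simple network whose strict level equals the
    cycle rank of *G*.
    """
    leaves = list(leaves)
    if len(leaves) < 2:
        raise NetworkError("at least two leaves are required")
    base = nx.MultiGraph()
    mapping = {v: f"g{v}" for v in G.multigraph.nodes()}
    for u, v, k in G.multigraph.edges(keys=True):
        base.add_edge(mapping[u], mapping[v])
    for leaf in leaves:
        if leaf in base:
            raise NetworkError(f"leaf label {leaf!r} collides with a vertex")

    results = []
    buckets = {}

    def emit(H):
        # H must now be simple
        if nx.number_of_selfloops(H):
            return
        plain = set()
        for u, v in H.edges():
            e = _norm_edge(u, v)
            if e in plain:
                return
            plain.add(e)
        try:
            net = PhyloNetwork.from_edges(sorted(plain))
        except NetworkError:
            return
        if net.leaf_set != frozenset(leaves) or not is_simple_network(net):
            return
        h = network_hash(net)
        reps = buckets.setdefault(h, [])
        if any(networks_isomorphic(net, R) for R in reps):
            return
        reps.append(net)
        results.append(net)

    def rec(H, remaining, counter):
        if not remaining:
            emit(H)
            return
        leaf = remaining[0]
        w = f"a{counter}"
        for u, v, k in sorted(H.edges(keys=True)):
            H2 = nx.MultiGraph(H)
            H2.remove_edge(u, v, key=k)
            H2.add_edge(u, w)
            H2.add_edge(w, v)
            H2.add_edge(w, leaf)
            rec(H2, remaining[1:], counter + 1)

    rec(base, leaves, 0)
    return results


# ---------------------------------------------------------------------------
# Random tree-based networks and tree enumeration
# ---------------------------------------------------------------------------

def _random_tree_graph(X, rng):
    """Uniform random unrooted binary tree on X by sequential leaf insertion
    (attaching leaf i+1 to a uniformly chosen edge of a uniform tree on i
    leaves is the classic bijection with uniform trees on i+1 leaves)."""
    X = sorted(X)
    G = nx.Graph()
    if len(X) == 1:
        G.add_node(X[0])
        return G
    if len(X) == 2:
        G.add_edge(X[0], X[1])
        return G
    centre = "i0"
    G.add_edges_from((centre, x) for x in X[:3])
    for j, x in enumerate(X[3:], start=1):
        edges = sorted(map(tuple, map(sorted, G.edges())))
        u, v = edges[rng.randrange(len(edges))]
        w = f"i{j}"
        G.remove_edge(u, v)
        G.add_edges_from([(u, w), (w, v), (w, x)])
    return G


def random_tree_based_network(X, extra_edges=0, seed=0, max_attempts=1000):
    """A seeded random tree-based network with its support-tree witness.

    Starts from a uniform random phylogenetic tree on *X*; each extra edge
    subdivides two distinct edges of the current support tree and joins the
    two fresh subdivision points, so the subdivided tree remains a spanning
    tree with leaf set X throughout and is returned as the witness.
    Returns ``(network, support_tree)``.
    """
    X = sorted(X)
    if len(X) < 2 and extra_edges:
        raise NetworkError("extra edges require at least two leaves")
    rng = random.Random(seed)
    G = _random_tree_graph(X, rng)
    tree_edges = set(_norm_edge(u, v) for u, v in G.edges())
    counter = 0
    for _ in range(extra_edges):
        for attempt in range(max_attempts):
            cands = sorted(tree_edges)
            if len(cands) < 2:
                raise NetworkError("not enough tree edges to add another edge")
            e1, e2 = rng.sample(cands, 2)
            m1, m2 = f"m{counter}", f"m{counter + 1}"
            if G.has_edge(m1, m2):  # cannot happen (fresh labels); guard anyway
                continue
            counter += 2
            for (a, b), m in ((e1, m1), (e2, m2)):
                G.remove_edge(a, b)
                G.add_edges_from([(a, m), (m, b)])
                tree_edges.remove(_norm_edge(a, b))
                tree_edges.add(_norm_edge(a, m))
                tree_edges.add(_norm_edge(m, b))
            G.add_edge(m1, m2)
            break
        else:
            raise NetworkError("could not place an extra edge")
    net = PhyloNetwork(G, leaves=X)
    witness = SupportTree.of(net, tree_edges) if len(net) > 1 else SupportTree(
        frozenset(net.vertices), frozenset(), net.leaves
    )
    return net, witness


def enumerate_phylo_trees(X):
    """All unrooted binary phylogenetic trees on X, for 1 <= |X| <= 6.

    Counts follow the double factorial (2|X|-5)!!: 1, 1, 1, 3, 15, 105.
    """
    X = sorted(X)
    if not 1 <= len(X) <= 6:
        raise ValueError("tree enumeration supported for 1 <= |X| <= 6")
    if len(X) == 1:
        return [PhyloTree(_one_node(X[0]))]
    if len(X) == 2:
        return [PhyloTree(nx.Graph([(X[0], X[1])]))]
    base = nx.Graph(("i0", x) for x in X[:3])
    trees = [base]
    for j, x in enumerate(X[3:], start=1):
        nxt = []
        w = f"i{j}"
        for T in trees:
            for u, v in sorted(map(tuple, map(sorted, T.edges()))):
                T2 = nx.Graph(T)
                T2.remove_edge(u, v)
                T2.add_edges_from([(u, w), (w, v), (w, x)])
                nxt.append(T2)
        trees = nxt
    return [PhyloTree(T) for T in trees]


def _one_node(v):
    G = nx.Graph()
    G.add_node(v)
    return G


# ---------------------------------------------------------------------------
# The strict level-5 counterexample and the pendant gadget
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=1)
def find_level5_counterexample():
    """The first (in canonical enumeration order) simple strict level-5
    network on {x, y} that is not tree-based.

    Produced by exhaustive search over pendant insertions into the connected
    cubic multigraphs on 8 vertices; the result has 12 vertices
    (= 2(|X| - 1 + k) with |X| = 2, k = 5), is proper and simple.  Existence
    is guaranteed: levels up to 4 are always tree-based but level 5 is not.
    """
    for G in iter_cubic_multigraphs(8):
        for net in networks_from_generator(G, ("x", "y")):
            if not is_tree_based(net):
                assert strict_level(net) == 5 and len(net) == 12
                return net
    raise AssertionError(
        "no level-5 counterexample found; the enumeration or the solver is broken"
    )


def replace_pendant_with_gadget(N, leaf, gadget):
    """Replace the pendant edge at *leaf* by a two-leaf gadget network.

    The gadget's first leaf side is welded onto the former leaf's neighbour
    and its second leaf takes over the name of *leaf*, so the taxon set is
    unchanged.  Grafting a non-tree-based strict level-5 gadget onto any
    network of strict level >= 5 leaves the level unchanged and destroys
    tree-basedness.
    """
    if leaf not in N.leaf_set:
        raise NetworkError(f"{leaf!r} is not a leaf of N")
    if len(gadget.leaves) != 2:
        raise NetworkError("gadget must have exactly two leaves")
    gx, gy = gadget.leaves
    (w,) = list(N.graph.neighbors(leaf))

    # relabel gadget vertices away from N's namespace
    taken = set(N.graph)
    mapping = {}
    for v in gadget.vertices:
        lbl = fresh_label(taken, "q")
        mapping[v] = lbl
        taken.add(lbl)
    Gg = nx.relabel_nodes(nx.Graph(gadget.graph), mapping)
    gx, gy = mapping[gx], mapping[gy]

    if len(Gg) == 2:  # single-edge gadget: identity replacement
        G = nx.Graph(N.graph)
        return PhyloNetwork(G)
    (px,) = list(Gg.neighbors(gx))
    G = nx.Graph(N.graph)
    G.remove_node(leaf)
    Gg.remove_node(gx)
    G.add_edges_from(Gg.edges())
    if G.has_edge(w, px):
        raise NetworkError("gadget identification would create a parallel edge")
    G.add_edge(w, px)
    G = nx.relabel_nodes(G, {gy: leaf})
    return PhyloNetwork(G, leaves=N.leaf_set)
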