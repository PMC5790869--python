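"""Readers and writers for the supported plain-text formats.

* ``.unet`` edge lists for unrooted networks: one edge per line (two
  whitespace-separated vertex labels), ``#`` comments and blank lines
  ignored; the single-vertex network is written as ``vertex <label>``.
  Leaves are inferred as the degree-1 vertices.  The writer emits sorted
  edges, so identical networks serialize to identical bytes.
* GraphML (undirected) via networkx, with an optional boolean ``is_leaf``
  vertex attribute that is verified against the degrees on read.
* Directed edge lists for rooted networks: ``u -> v`` per line, root
  inferred as the unique indegree-0 vertex.
* Newick for phylogenetic trees (dendropy parser; trees are written rooted
  at an internal vertex adjacent to the lexicographically smallest leaf).
"""

from __future__ import annotations

import io as _io
import os

import dendropy
import networkx as nx

from .network import NetworkError, PhyloNetwork, PhyloTree
from .rooted import Orientation, RootedPhyloNetwork

__all__ = [
    "read_unet", "write_unet", "loads_unet", "dumps_unet",
    "read_graphml", "write_graphml",
    "read_rooted", "write_rooted",
    "write_orientation", "read_orientation",
    "tree_to_newick", "tree_from_newick",
]


# -- .unet ------------------------------------------------------------------

def loads_unet(text, declared_leaves=None):
    G = nx.Graph()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "vertex":
            if len(parts) != 2:
                raise NetworkError(f"line {lineno}: expected 'vertex <label>'")
            G.add_node(parts[1])
        elif len(parts) == 2:
            G.add_edge(parts[0], parts[1])
        else:
            raise NetworkError(f"line {lineno}: expected two labels, got {line!r}")
    return PhyloNetwork(G, leaves=declared_leaves)


def dumps_unet(N, header=None):
    out = _io.StringIO()
    if header:
        for line in header.splitlines():
            out.write(f"# {line}\n")
    if len(N) == 1:
        out.write(f"vertex {N.vertices[0]}\n")
    else:
        for u, v in N.edges:
            out.write(f"{u} {v}\n")
    return out.getvalue()


def read_unet(path, declared_leaves=None):
    with open(path) as fh:
        return loads_unet(fh.read(), declared_leaves)


def write_unet(N, path, header=None):
    with open(path, "w") as fh:
        fh.write(dumps_unet(N, header=header))


# -- GraphML ----------------------------------------------------------------

def read_graphml(path):
    G = nx.read_graphml(path)
    if G.is_directed():
        raise NetworkError("expected an undirected GraphML graph")
    G = nx.Graph(G)
    declared = {
        v for v, d in G.nodes(data=True)
        if str(d.get("is_leaf", "")).lower() in ("true", "1")
    }
    H = nx.Graph()
    H.add_nodes_from(str(v) for v in G.nodes())
    H.add_edges_from((str(u), str(v)) for u, v in G.edges())
    return PhyloNetwork(H, leaves={str(v) for v in declared} or None)


def write_graphml(N, path):
    G = nx.Graph()
    X = N.leaf_set
    for v in N.vertices:
        G.add_node(v, is_leaf=(v in X))
    G.add_edges_from(N.edges)
    nx.write_graphml(G, path)


# -- rooted directed edge lists --------------------------------------------

def loads_rooted(text):
    D = nx.DiGraph()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "vertex" and len(parts) == 2:
            D.add_node(parts[1])
            continue
        if len(parts) != 3 or parts[1] != "->":
            raise NetworkError(f"line {lineno}: expected 'u -> v', got {line!r}")
        D.add_edge(parts[0], parts[2])
    return RootedPhyloNetwork(D)


def dumps_rooted(M, header=None):
    out = _io.StringIO()
    if header:
        for line in header.splitlines():
            out.write(f"# {line}\n")
    if len(M) == 1:
        out.write(f"vertex {M.root}\n")
    else:
        for t, h in M.arcs:
            out.write(f"{t} -> {h}\n")
    return out.getvalue()


def read_rooted(path):
    with open(path) as fh:
        return loads_rooted(fh.read())


def write_rooted(M, path, header=None):
    with open(path, "w") as fh:
        fh.write(dumps_rooted(M, header=header))


# -- orientation tables -----------------------------------------------------

def write_orientation(o, path, header=None):
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for t, h in o.arcs:
            fh.write(f"{t} -> {h}\n")


def read_orientation(path):
    arcs = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            t, arrow, h = line.split()
            if arrow != "->":
                raise NetworkError(f"bad orientation line {line!r}")
            arcs.append((t, h))
    return Orientation(arcs)


# -- Newick -----------------------------------------------------------------

def tree_to_newick(T):
    """Serialize a phylogenetic tree as Newick.

    Unrooted convention: the string is rooted at an internal vertex adjacent
    to the lexicographically smallest leaf (trees with one or two leaves are
    written as ``x;`` / ``(x,y);``).
    """
    G = T.graph
    if len(G) == 1:
        return f"{T.vertices[0]};"
    if len(T.leaves) == 2:
        a, b = T.leaves
        return f"({a},{b});"
    root = next(iter(sorted(G.neighbors(min(T.leaves)))))
    X = T.leaf_set

    def render(v, parent):
        kids = sorted(w for w in G.neighbors(v) if w != parent)
        if not kids:
            return v
        inner = ",".join(render(w, v) for w in kids)
        return f"({inner})"

    return f"{render(root, None)};"


def tree_from_newick(text):
    """Parse a Newick string into a :class:`PhyloTree`.

    Bifurcating-root strings are accepted; the artificial degree-2 root is
    suppressed.  Internal vertices are auto-named ``i#``.
    """
    tree = dendropy.Tree.get(data=text, schema="newick")
    G = nx.Graph()
    counter = [0]
    names = {}

    def name_of(node):
        if node in names:
            return names[node]
        if node.is_leaf():
            lbl = node.taxon.label if node.taxon else node.label
            if lbl is None:
                raise NetworkError("leaf without a label in Newick input")
            names[node] = str(lbl)
        else:
            names[node] = f"i{counter[0]}"
            counter[0] += 1
        return names[node]

    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            G.add_edge(name_of(node), name_of(child))
    if len(G) == 0:  # single-leaf tree
        seed = tree.seed_node
        G.add_node(name_of(seed))
        return PhyloTree(G)
    # suppress an artificial degree-2 root left by rooted Newick
    for v in [v for v in G if G.degree(v) == 2]:
        a, b = G.neighbors(v)
        G.remove_node(v)
        G.add_edge(a, b)
    return PhyloTree(G)


def detect_format(path):
    ext = os.path.splitext(path)[1].lower()
    if ext in (".graphml", ".xml"):
        return "graphml"
    return "unet"
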