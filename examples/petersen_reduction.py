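"""The Petersen reduction: Hamiltonicity <-> tree-basedness.

Subdividing an edge of a cubic graph twice and hanging leaves x, y on the
subdivision points gives a two-leaf network C_e(x,y) that is tree-based iff
the cubic graph has a Hamiltonian cycle through some edge.  The Petersen
graph is the classic non-Hamiltonian cubic graph, so its reduction is a
simple, proper, strict level-6 network with no support tree at all.
"""

import treespan as ts

C = ts.petersen()
print(f"Petersen graph: {len(C)} vertices, {len(C.edges)} edges, "
      f"Hamiltonian: {ts.is_hamiltonian(C)}")

N = ts.cubic_to_network(C, C.edges[0])
print(f"reduction C_e(x,y): |V|={len(N)}, leaves={list(N.leaves)}")
print(f"  simple: {ts.is_simple_network(N)}  proper: {ts.is_proper(N)}  "
      f"strict level: {ts.strict_level(N)}")
print(f"  tree-based: {ts.is_tree_based(N)}")

# contrast with K4, the smallest Hamiltonian cubic graph
K = ts.complete_graph_k4()
M = ts.cubic_to_network(K, K.edges[0])
S = ts.find_support_tree(M)
print(f"K4 reduction: strict level {ts.strict_level(M)}, "
      f"tree-based: {S is not None}")
print(f"  one support tree: {S.sorted_edges()}")
# Interpretation: the level-6 Petersen network cannot be drawn as a tree
# plus extra edges, while the level-3 K4 network can.
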