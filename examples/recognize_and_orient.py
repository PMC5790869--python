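"""Recognition with a witness, base-trees, and the rooted orientation.

A random tree-based network is built from a random tree by repeatedly
subdividing two support-tree edges and joining the subdivision points (the
classic reticulogram construction).  We recover a support tree by search,
suppress its degree-2 vertices into a base-tree, and orient the network
away from a leaf to obtain a rooted tree-based network on the remaining
taxa.
"""

import treespan as ts
from treespan.io import dumps_rooted, tree_to_newick

N, witness = ts.random_tree_based_network(list("abcdef"), extra_edges=3, seed=11)
print(f"network: |V|={len(N)}, |E|={N.graph.number_of_edges()}, "
      f"strict level {ts.strict_level(N)}, blobs: {len(ts.blobs(N))}")

S = ts.find_support_tree(N)
print(f"support tree found with {len(S.edges)} edges "
      f"(witness had {len(witness.edges)})")

T = ts.base_tree_of(N, S)
print("base tree:", tree_to_newick(T))

o, M = ts.orient_from_support_tree(N, "a", S)
print(f"oriented away from leaf 'a': rooted network on {list(M.leaves)}, "
      f"root {M.root!r}, reticulations: {list(M.reticulations)}")
print(f"rooted tree-based: {ts.is_rooted_tree_based(M)}")
print(dumps_rooted(M), end="")
# Interpretation: the orientation theorem makes the unrooted notion agree
# with the rooted one once any leaf is chosen as an outgroup position.
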