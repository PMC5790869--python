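"""Universal tree-based networks: one network, every tree as a base-tree.

For any taxon set X there is a tree-based network having every phylogenetic
tree on X as a base-tree.  At desk scale we find one by bounded randomized
search: draw random tree-based networks and test all (2|X|-5)!! trees for
base-tree containment.
"""

import treespan as ts
from treespan.io import tree_to_newick

X = ["a", "b", "c", "d"]
trees = ts.enumerate_phylo_trees(X)
print(f"{len(trees)} phylogenetic trees on {X}")

net = ts.find_universal_network(X, seed=0, extra_edges=3, max_tries=100)
print(f"universal network found: |V|={len(net)}, "
      f"strict level {ts.strict_level(net)}")
for T in trees:
    print(f"  base-tree {tree_to_newick(T)} -> {ts.is_based_on(net, T)}")

# a single tree is never universal once |X| >= 4: it is based only on itself
quartet = trees[0]
print("a lone quartet tree universal?", ts.is_universal(quartet))
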