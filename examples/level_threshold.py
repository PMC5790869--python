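"""The level threshold for guaranteed tree-basedness.

Every simple two-leaf network of level k arises by inserting the two
pendant leaves into a connected cubic multigraph on 2(k-1) vertices.
Enumerating those generators exhaustively shows that all proper networks of
level <= 4 are tree-based, while level 5 already contains a counterexample.
(The full level-5 sweep takes a couple of seconds; the low levels are
instant.)
"""

import treespan as ts

for n in (2, 4, 6):
    level = n // 2 + 1
    nets = []
    for G in ts.enumerate_cubic_multigraphs(n):
        nets += ts.networks_from_generator(G, ("x", "y"))
    all_tb = all(ts.is_tree_based(N, use_shortcuts=False) for N in nets)
    print(f"level {level}: {len(nets)} simple networks on {{x,y}}, "
          f"all tree-based: {all_tb}")

cx = ts.find_level5_counterexample()
print(f"level 5: first non-tree-based network found, |V|={len(cx)}, "
      f"strict level {ts.strict_level(cx)}, proper: {ts.is_proper(cx)}")
print("edges:", " ".join(f"{u}-{v}" for u, v in cx.edges))
# Interpretation: 4 is the largest level at which properness alone forces a
# support tree to exist; from level 5 on, recognition requires search.
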