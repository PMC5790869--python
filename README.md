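# treespan

Tree-based **unrooted phylogenetic networks**: decomposition, exact
recognition with witnesses, level analysis, the rooted orientation
correspondence, and the generator enumerations that let the theory be
verified computationally at desk scale.

## The problem

An unrooted phylogenetic network *N* on a taxon set *X* is a connected
simple graph in which every vertex has degree 1 or 3 and whose degree-1
vertices are exactly *X*.  Such networks generalize unrooted binary trees
and are used to represent reticulate evolution — horizontal gene transfer,
hybridization — or uncertainty about it.  Reticulogram software builds
networks by adding edges into a phylogenetic tree; the networks obtainable
this way are exactly the **tree-based** ones: those with a **support
tree**, a spanning tree whose leaf set equals *X*.  A **base-tree** of *N*
is a support tree with its degree-2 vertices suppressed.

This package answers, exactly and with witnesses, the questions a
practitioner or a combinatorialist asks about this notion:

- Is *N* tree-based?  (NP-complete; solved here by blob-wise decomposition
  plus a pruned spanning-tree backtracking search, exact at desk scale.)
- Is a given tree *T* a base-tree of *N*?  Is it merely *displayed*?
- What is the **level** of *N* (the maximum cycle rank over its **blobs**,
  the maximal cut-edge-free subgraphs)?  Properness plus level ≤ 4 already
  forces tree-basedness; level 5 does not, and the package finds the
  smallest counterexample by exhaustive generator enumeration.
- How do unrooted and rooted tree-based networks correspond?  Orienting a
  support tree away from a leaf *x* and removing *x* yields a rooted
  tree-based network on *X* − {x}, and the construction inverts.
- Hamiltonicity of a cubic graph *C* is equivalent to tree-basedness of
  the two-leaf network *C<sub>e</sub>(x,y)* (subdivide edge *e* twice, hang
  leaves on the subdivision points) — the reduction behind the hardness
  results, runnable here in both directions.

## Worked example

```python
import treespan as ts

C = ts.petersen()                      # Kneser (5,2) construction
N = ts.cubic_to_network(C, C.edges[0]) # the two-leaf reduction
ts.strict_level(N)                     # -> 6
ts.is_simple_network(N)                # -> True
ts.is_tree_based(N)                    # -> False   (Petersen is not Hamiltonian)

K = ts.complete_graph_k4()
M = ts.cubic_to_network(K, K.edges[0])
S = ts.find_support_tree(M)            # a witness support tree
ts.base_tree_of(M, S).edges            # -> (('x', 'y'),)
```

Running `python examples/petersen_reduction.py` prints:

```
Petersen graph: 10 vertices, 15 edges, Hamiltonian: False
reduction C_e(x,y): |V|=14, leaves=['x', 'y']
  simple: True  proper: True  strict level: 6
  tree-based: False
K4 reduction: strict level 3, tree-based: True
  one support tree: (('a', 'c'), ('a', 'u0'), ('b', 'd'), ('b', 'u1'), ('c', 'd'), ('u0', 'x'), ('u1', 'y'))
```

The level-6 Petersen network admits no support tree, while the level-3 K4
network does — and its support tree is an x–y Hamiltonian path, witnessing
a Hamiltonian cycle of K4 through the chosen edge.

`python examples/level_threshold.py` enumerates every simple two-leaf
network of level 2–4 from cubic multigraph generators (1, 4, and 22
networks respectively), confirms each is tree-based, and then exhibits the
first strict level-5 network that is not:

```
level 2: 1 simple networks on {x,y}, all tree-based: True
level 3: 4 simple networks on {x,y}, all tree-based: True
level 4: 22 simple networks on {x,y}, all tree-based: True
level 5: first non-tree-based network found, |V|=12, strict level 5, proper: True
```

The other examples cover recognition + orientation on random reticulograms
(`recognize_and_orient.py`) and the bounded search for a universal network
— one having *every* tree on X as a base-tree (`universal_network.py`).

## Command line

A thin CLI wraps the library (exit codes: 0 yes, 1 no, 2 error/undecided):

```sh
treespan gen fixture --name petersen_net --out p.unet
treespan check p.unet --mode tree-based        # exit 1
treespan check p.unet --mode level             # strict_level: 6
treespan gen tree-based --leaves 6 --extra 3 --seed 1 --out n.unet
treespan orient n.unet --leaf t1 --out rooted.txt --table orientation.txt
```

Networks are plain-text edge lists (`.unet`) or GraphML; trees are Newick;
rooted networks are `u -> v` directed edge lists.

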