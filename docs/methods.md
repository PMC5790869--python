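# Methods

## The model

An unrooted phylogenetic network on a taxon set X is a connected simple
graph with all degrees in {1, 3} whose degree-1 vertices are exactly X; the
single-vertex graph on one taxon is admitted as the degenerate one-leaf
network.  A support tree is a spanning tree whose degree-1 vertices are
exactly X; a network admitting one is tree-based.  A base-tree is a support
tree with its degree-2 vertices suppressed.  A tree T is displayed when
some (not necessarily spanning) subtree with leaf set X suppresses to T.

Structural vocabulary: a cut-edge is a bridge, trivial when one side of its
removal is a single vertex; a network is proper when every cut-edge splits
X into two non-empty parts and simple when every cut-edge is trivial; a
blob is a maximal cut-edge-free subgraph with more than one vertex, and the
simple network B_N of a blob is the blob plus its incident cut-edges, the
outer endpoints acting as its leaves.  The strict level is the maximum
cycle rank |E(B)| − |V(B)| + 1 over blobs; "level-k" is used throughout
with at-most semantics (`is_level(N, k)` ⇔ `strict_level(N) ≤ k`), so a
level-1 network is also level-2.  Both faces are exposed because the
threshold statements ("proper level-4 networks are tree-based") read
naturally with ≤ while the counterexamples are pinned by the strict value.

## Recognition

Deciding tree-basedness is NP-complete (the cubic-Hamiltonicity reduction
is in `constructions`), so the solver is an exact search engineered for
desk-scale instances:

1. **Blob decomposition.**  N is tree-based iff every B_N is, and every
   cut-edge lies in every support tree.  The solver therefore splits into
   independent per-blob subproblems and splices per-blob trees with the
   cut-edges.  This bounds the exponential part by the largest blob.
2. **Constrained spanning-tree backtracking** inside a blob: edges in
   sorted order, include-before-exclude, a union–find forbids cycles, and
   per-vertex degree accounting prunes any branch in which a leaf can no
   longer reach tree-degree exactly 1 or an internal vertex tree-degree at
   least 2.  The same routine, run on induced subgraphs over subsets of
   internal vertices, enumerates the non-spanning subtrees needed by the
   display check and the definitional fully-tree-based verifier.
3. **Sound shortcuts** (on by default, disabled via `use_shortcuts=False`):
   an improper network is never tree-based; a proper network of strict
   level ≤ 4 always is.  The cross-validation tests always run the pure
   search so the shortcuts are themselves tested claims, not assumptions.

Tie-breaks are fixed everywhere (sorted vertices, sorted edges), so
searches, enumerations and witnesses are deterministic.  All searches take
an optional node-expansion `budget`; exhausting it raises `UndecidedError`,
which the CLI maps to exit code 2 — "undecided" is never conflated with
"no".

Tree comparison with labelled leaves (base-tree containment, display,
dedup) uses a canonical form rooted at the lexicographically smallest leaf
with sorted child subtrees; internal vertices are anonymous.

The fully-tree-based test returns the level-1 characterization verdict
(`strict_level ≤ 1`); the definitional verifier — exhaustive subtree
enumeration — is a separate function so the equivalence is checked, not
assumed, on every fixture with ≤ 14 vertices.

## Rooted correspondence

A rooted phylogenetic network is a binary rooted DAG (root 0-in/2-out,
leaves 1-in/0-out, tree vertices 1-in/2-out, reticulations 2-in/1-out);
the single-vertex digraph is allowed as the degenerate case so that
orienting a two-leaf network has a value.  `orient_from_support_tree`
follows the existence proof literally: tree edges point away from the
chosen leaf x, vertices are visited in BFS-from-x order (a topological
order of the oriented tree, with lexicographic tie-break for determinism),
and each remaining edge is directed away from its earlier endpoint — all
arcs therefore go forward in that order, so acyclicity is structural.
Removing x yields the rooted network, rooted at x's former neighbour.

Rooted tree-basedness is decided exactly by iterating over the in-arc kept
at each reticulation (2^r cases): in a DAG where every non-root vertex
keeps indegree 1 the kept arcs automatically form a spanning arborescence,
so the only check is that no internal vertex is stranded as a sink.  This
is exponential only in the reticulation count, which is adequate here; the
known polynomial algorithm for the rooted problem is deliberately not
implemented.

Re-attachment hangs the new leaf directly on the root (the root's degree
becomes 3), making `attach_leaf_at_root` the exact inverse of the deletion
in the orientation construction.  An intermediate degree-2 vertex, as a
literal reading of the universality argument would introduce, is invalid
in this degree regime and is not used.

Universality (every tree on X is a base-tree) is checked by enumerating
all (2|X|−5)!! trees — practical for |X| ≤ 5 — and universal networks are
*found* by bounded randomized search over random tree-based networks; no
explicit universal construction is implemented.

## Generators and enumeration

**Simple level-k networks on two leaves** are produced exhaustively from
connected cubic multigraphs on 2(k−1) vertices (loops and parallel edges
allowed): each pendant-leaf insertion subdivides a multigraph edge, and
placements that leave a loop, a parallel pair, or a non-trivial cut-edge
are discarded.  Every output is a valid simple network whose strict level
equals the generator's cycle rank and whose vertex count obeys
|V| = 2(|X| − 1 + k); the enumeration tests assert both identities and the
companion count q = 2k − 2 of vertices outside pendant edges.

The multigraph enumeration scans labelled adjacency assignments (loops
restricted to a vertex prefix — sound, since any isomorphism class has such
a representative) and deduplicates exactly: a color-refinement certificate
buckets candidates, and a class-constrained backtracking isomorphism test
settles each bucket.  Counts obtained: 2, 5, 17, 71 connected cubic
multigraphs on 2, 4, 6, 8 vertices; the n = 2 count is checked against the
two hand-enumerable graphs and the n = 4 count against an independent
orbit-counting brute force over all labelled adjacency assignments.
Network-level dedup (leaf labels fixed) uses a Weisfeiler–Lehman hash for
bucketing and VF2 for the exact check.

**The strict level-5 counterexample** is not transcribed from any drawing:
it is the first network, in canonical enumeration order, among all pendant
insertions into the 71 generators on 8 vertices that the pure search
reports non-tree-based.  The search early-exits (about two seconds) and
the result is cached per process; any valid counterexample serves all
downstream uses, including the pendant-replacement gadget that produces
strictly level-k non-tree-based networks for every k ≥ 5.

**Random tree-based networks** start from a uniform random unrooted binary
tree (sequential leaf insertion — attaching leaf i+1 to a uniform edge of a
uniform i-leaf tree is the standard bijection, so topologies are uniform).
Each extra edge subdivides two distinct edges *of the current support tree*
and joins the two fresh subdivision points.  Restricting the subdivided
edges to the support tree (rather than to arbitrary edges, which could
place later subdivision points on earlier added edges) is what keeps the
growing subdivided tree a spanning tree with leaf set X at every step, so
the construction tree is returned as a valid witness; it is also exactly
the reticulogram paradigm the package models.  Such additions can never
create loops or parallel edges, but a rejection cap (default 1000) guards
the degenerate configurations (e.g. two leaves with one extra edge, which
is impossible and reported as an error).  All randomness flows through a
seeded `random.Random`; identical seed and parameters give identical
graphs, files and bytes.

### What the generator does and does not emulate

The random generator reproduces the *combinatorial* generative model of
reticulograms: a true underlying tree plus a handful of reticulation
edges.  It does not model branch lengths, non-binary vertices, sampling
noise, or any sequence-level signal — so passing tests certify the
combinatorial theory (decomposition, recognition, orientation) on exactly
the class of networks the theory is about, and say nothing about inferring
such networks from data.

## Problem sizes and budgets

Chosen so the full test suite runs in well under a minute and the
acceptance script in about half a minute on one CPU: generator enumeration
up to 8 multigraph vertices (levels ≤ 5; 12-vertex networks), simple cubic
graphs up to 8 vertices plus the Petersen graph for the Hamiltonicity
equivalence, brute-force spanning-tree and subtree oracles up to 14-vertex
networks, ≥ 100 seeded random networks for the orientation round trip, and
tree enumeration up to |X| = 6 (105 trees).  These are desk-scale choices,
not algorithmic limits; the searches remain exact at any size the user is
willing to wait for, with the `budget` parameter as the escape hatch.

## Known limitations

- Non-binary networks, branch lengths and multigraph *network* types are
  out of scope (multigraphs occur only as generators).
- `is_based_on`/`displays` enumerate support trees/subtrees and are
  exponential; they are meant for small instances and witnesses, not bulk
  screening.
- Multigraph enumeration is capped at 8 vertices (level 5); no attempt is
  made at isomorph-free generation at scale.
- Leaf deletion can be degenerate (suppression creating a parallel edge,
  e.g. deleting a leaf of the triangle-with-pendants network); the result
  is flagged explicitly rather than silently returned as a multigraph.
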