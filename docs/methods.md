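# Methods

## Model and procedure

The package treats phylogenetic uncertainty from incomplete species
sampling as a Monte-Carlo problem. Input: a rooted phylogeny `T0` in
Newick format with branch lengths; a list of missing species, each tagged
with the label of its most derived consensus clade (MDCC) — the smallest
clade known to contain it; and a replicate count *m*. Output: *m* expanded
trees, each with every missing taxon attached at an independently drawn
random point inside its MDCC, and optionally one patristic distance matrix
per replicate. Downstream comparative statistics (phylogenetic diversity,
regression on variance–covariance matrices, …) are deliberately out of
scope: the matrices are the hand-off point.

### Preorder indexing

Nodes are identified by DFS preorder rank (root = 1, children in input
order). Preorder makes every subtree a contiguous rank block
`[u, u + descendants[u]]`, which is what turns random insertion-point
choice into interval arithmetic and the subtree branch-length total into a
difference of two prefix sums (`sum_lengths`). Trees need not be binary;
polytomies are handled everywhere, and no algorithm assumes bifurcation.
Missing branch lengths default to 1.0 with a warning (a strict mode
rejects them); negative lengths are always rejected.

### Insertion-point sampling

*Node-based*: uniform over the inclusive interval
`[v_mdcc, v_mdcc + descendants[v_mdcc]]`. Inclusivity means the clade root
itself can be drawn, in which case the taxon attaches on the branch above
the clade — the documented consequence of keeping the interval closed at
both ends.

*Branch-based*: `r` uniform on `(0, σ]` where σ is the clade's internal
branch-length total; the cumulative coordinate `δ = sum_lengths[v_mdcc] + r`
is resolved to the node `p` with the smallest `sum_lengths[p] ≥ δ` by
binary search (lower bound — the only resolution rule consistent with the
package's reference example, where a draw of 4.2 in clade 7 must select
node 12). The numeric draw uses `uniform[0, σ)` with 0 remapped to the
smallest positive double, giving the half-open-above law on `(0, σ]`.
A leaf MDCC has σ = 0: `select_branch_based` raises, and the `expand`
driver falls back to the only feasible choice, the leaf's own branch.

### Attachment semantics

Both methods attach through a fresh internal node `w` bisecting the branch
*currently* immediately above the chosen node `p`: `w` takes `p`'s parent,
and holds `{p, new leaf}`. The two halves of the cut branch sum exactly to
its previous length, so all pairwise path lengths among pre-existing nodes
are invariant — the property that makes averages of replicate matrices
unbiased for the original distances. When `p` is the root, `w` becomes the
new root with a zero-length stem. Repeated insertions at the same original
node nest in PUT-file order, each splitting the current branch; insertion
targets are always original-tree nodes, which is what permits a single
preprocessing pass regardless of *m*.

Two conventions the input format does not determine:

* **Split position** on the cut branch: the branch-based method uses the
  offset implied by its own draw (`branch_length[p] − (sum_lengths[p] − δ)`
  from the parent end, rescaled proportionally if the branch was already
  shortened by an earlier nested insertion); the node-based method uses
  the midpoint by default (`split_policy="uniform"` optional).
* **Pendant length**: default `ultrametric` — the pendant extends the new
  tip to the deepest tip depth of its MDCC subtree, so inserted taxa look
  contemporaneous with their clade; `fixed:X` is the alternative. Pendant
  policy never affects topology, chain structure, or original-leaf
  distances.

### Distances

`Dist[u,v] = dist_root[u] + dist_root[v] − 2·dist_root[LCA(u,v)]`. LCA
queries use a heavy-chain decomposition: descend from the root always into
the child with the most descendants (ties to the first child in input
order, fixed for determinism); bypassed children lead new chains. Chains
partition the nodes, every chain ends at a leaf, and #chains = #leaves.
A query repeatedly replaces whichever argument has the deeper chain leader
by that leader's parent; equal leader depths advance the larger-rank
leader (either is correct). Each jump exits a light subtree and therefore
at least halves the relevant subtree size, so each argument performs
O(log n) jumps; a full matrix costs O(n² log n) all-nodes or
O(|leaves|² log n) patristic. Only the upper triangle is computed and
mirrored. Distances accumulate in double precision; equality checks in the
test suite use relative tolerance 1e-9.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `method` | `branch` | insertion law; branch-based weights by branch length (the configuration used for the package's headline workflow; results of the two laws differ little in practice) |
| `replicates` (*m*) | 100 | number of expanded trees |
| `seed` | 0 | base seed; replicate *i* uses substream `(seed, i)`, so growing *m* never changes earlier replicates |
| `pendant_policy` | `ultrametric` | pendant branch length of inserted tips (units: branch-length units of the input tree) |
| `split_policy` | `midpoint` | node-based split point on the cut branch |
| matrix `scope` | `leaves-only` | patristic (tips) vs all-nodes matrices |
| writer `precision` | 6 significant digits | matrix text output; Newick output uses shortest-round-trip floats |

## Synthetic data

`synthetic.random_tree` grows random binary topologies by splitting a
uniformly chosen existing tip (Yule-like), with caterpillar and balanced
shapes as extremes, and unit / uniform / exponential branch-length laws.
It emulates what matters to these algorithms — tree size, balance, and
branch-length variation — and nothing else: no extinction, no
non-ultrametric rate structure, no sequence evolution, no polytomies
(though parsed polytomous trees are fully supported). Passing tests
therefore demonstrate algorithmic correctness on arbitrary rooted metric
trees, not biological realism of any particular tree shape.
`synthetic.example_tree` / `example_expanded_tree` are hand-checkable
13- and 23-node fixtures whose per-node quantities anchor the exact tests.

## Numerical and degenerate-case choices

* Ranks are 1-based with a 0 sentinel for "no parent"; arrays are numpy
  int64/float64.
* A single-node tree is legal everywhere (one chain, empty interval
  arithmetic, zero matrix).
* Single-child roots (legal Newick) are accepted.
* Duplicate leaf labels are rejected at indexing; internal labels are
  optional, must be unique to be addressable as MDCCs, and an opt-in flag
  auto-labels unlabeled internal nodes by preorder rank.
* The node-based chi-square checks in the suite use fixed seeds; sampling
  assertions use p > 0.001 so they are robust yet still falsifiable.

## Problem sizes used in the test suite

Exact worked-example checks run on the 13/23-node fixtures. Oracle
equivalence compares the heavy-chain matrix and LCA against brute-force
ancestor walks on 100 random trees of up to ~200 nodes. Sampling-law
recovery uses 10^5 draws. The desk-scale smoke run expands a 500-leaf tree
with 100 inserted taxa over 1000 replicates and computes one 600×600
patristic matrix; these sizes exercise the full pipeline at the scale of a
realistic single-clade study while keeping the default suite quick on one
CPU.

## Known limitations

* Pure-Python inner loops: the O(n² log n) matrix is asymptotically right
  but constant-factor slower than a compiled implementation; for very
  large trees (tens of thousands of tips) a vectorised or compiled backend
  would be the next step.
* Insertion is topology-only randomisation: no use of taxonomic distances,
  placement likelihoods, or posterior tree samples (each input tree is
  processed independently).
* Unrooted and reticulate (network) phylogenies are out of scope, as are
  NEXUS/phyloXML I/O and variance–covariance transformation of matrices.
* The ultrametric pendant policy assumes the input clade depths are
  meaningful (e.g. time-calibrated); on trees with wildly heterogeneous
  rates a fixed pendant length may be preferable.
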