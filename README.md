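# phyloexpand

Monte-Carlo propagation of phylogenetic uncertainty for comparative
analyses: random expansion of an incomplete phylogeny with
clade-constrained missing taxa, and fast patristic distance matrices for
the resulting replicate trees.

## The problem

Molecular phylogenies are almost always incomplete. For a species missing
from the tree — a *phylogenetically uncertain taxon* (PUT) — taxonomy or
morphology usually pins down the smallest clade certain to contain it, its
*most derived consensus clade* (MDCC), but not its exact position. Dropping
such species biases comparative analyses; placing them at a single guessed
position hides the uncertainty. The expanded-tree approach instead draws
*m* replicate trees, each with every PUT attached at a random point inside
its MDCC, and replicates the downstream analysis over the *m* patristic
distance matrices; the spread across replicates estimates the phylogenetic
uncertainty. This only works at scale if both steps are fast.

## Algorithms

**Expansion.** One preorder DFS pass over the input tree `T0` computes, for
every node `u`, the descendant count `descendants[u]` and the cumulative
branch length `sumLengths[u]` along the traversal. Because a preorder
subtree is the contiguous rank block `[v, v + descendants[v]]`, each random
insertion needs no traversal:

* *node-based* — draw the attachment node uniformly from the integer
  interval `[v_mdcc, v_mdcc + descendants[v_mdcc]]`: O(1);
* *branch-based* — draw `r ~ U(0, σ]` with
  `σ = sumLengths[v_mdcc + descendants[v_mdcc]] − sumLengths[v_mdcc]` (the
  clade's total branch length), and binary-search the prefix sums for the
  smallest `sumLengths[p] ≥ sumLengths[v_mdcc] + r`: long branches are
  proportionally more likely to be split, at O(log n) per insertion.

The new leaf attaches through a fresh internal node bisecting the branch
above the chosen node, so all distances among pre-existing taxa are exactly
preserved. Expanding *m* trees costs O(|T0| + |S|) or
O(|T0| + |S|·log|T0|) per replicate beyond the single preprocessing pass.

**Distances.** With root distances precomputed,
`Dist[u,v] = distRoot[u] + distRoot[v] − 2·distRoot[LCA(u,v)]`. The tree is
partitioned into *heavy chains* (always descend into the child with the
most descendants; every bypassed child leads a new chain; #chains =
#leaves). An LCA query jumps chain-by-chain — whichever argument sits in
the chain with the deeper leader moves to that leader's parent — in
O(log n) jumps, giving an all-pairs matrix in O(n² log n) rather than the
naive O(n³).

## Worked example

The 13-node reference tree (unit branch lengths, nodes labeled by preorder
rank, leaves 3, 4, 6, 9, 10, 12, 13) with five PUTs:

```python
import phyloexpand as px

newick = "((3:1,4:1)2:1,(6:1,((9:1,10:1)8:1,(12:1,13:1)11:1)7:1)5:1)1;"
t0 = px.build_indexed_tree(px.read_newick(newick)[0])
px.preprocess_expansion(t0)

print("sigma(7)      =", px.subtree_length_sum(t0, 7))
print("interval(7)   =", t0.subtree_interval(7))
print("r=4.2 -> node", px.select_branch_based(t0, 7, r=4.2).insertion_node)

idx = px.heavy_chain_decomposition(t0)
print("LCA(6,13)     =", px.lca(idx, t0, 6, 13))
print("Dist(6,13)    =", px.node_distance(t0, idx, 6, 13))

puts = px.resolve_mdccs(px.read_put_file("16 7\n18 9\n20 11\n22 2\n24 2\n"), t0)
trees = px.expand(t0, puts, px.ExpansionConfig(method="branch", replicates=3, seed=7))
print("replicate 0   =", trees[0].node_count, "nodes,", trees[0].leaf_count, "leaves")

mats = list(px.matrices_for_replicates(trees))
print("matrix shape  =", mats[0].values.shape)
print("d(3,13) rep0  =", mats[0].by_label("3", "13"))
```

prints

```
sigma(7)      = 6.0
interval(7)   = (7, 13)
r=4.2 -> node 12
LCA(6,13)     = 5
Dist(6,13)    = 4.0
replicate 0   = 23 nodes, 12 leaves
matrix shape  = (12, 12)
d(3,13) rep0  = 6.0
```

`sigma(7) = 6` is the total branch length inside clade 7, read off two
prefix sums; the interval `[7, 13]` is the node-based sampling range for
that clade; the draw `r = 4.2` lands on the branch above node 12.
`Dist(6,13) = 4` is the patristic distance between leaves 6 and 13 through
their lowest common ancestor (node 5). Each expanded replicate gains two
nodes per inserted taxon (one attachment node, one leaf), hence 23 nodes
and 12 leaves, and its 12×12 patristic matrix keeps all original-leaf
distances unchanged (`d(3,13)` is still 6).

The same workflow from the shell:

```bash
phyloexpand expand   --tree ref.nwk --puts puts.txt --replicates 100 --seed 7 -o expanded.nwk
phyloexpand distmat  --trees expanded.nwk --scope patristic --out mat_
phyloexpand pipeline --tree ref.nwk --puts puts.txt --replicates 100 --seed 7 --out mat_
phyloexpand simulate --leaves 500 --puts 100 --seed 1 --out-tree big.nwk --out-puts big.puts
```

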