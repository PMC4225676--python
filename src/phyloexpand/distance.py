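"""Node-to-node and patristic distance matrices via heavy-chain LCA.

The distance between two nodes of a rooted tree is

    Dist[u, v] = dist_root[u] + dist_root[v] - 2 * dist_root[LCA(u, v)]

so all-pairs distances reduce to fast lowest-common-ancestor queries.  The
tree is partitioned into *heavy chains*: starting from the root, each chain
repeatedly descends into the child with the most descendants until it
reaches a leaf; every child left behind leads a new chain.  Chains
therefore partition the nodes, each chain ends at a leaf, and the number
of chains equals the number of leaves.  An LCA query walks both arguments
chain-by-chain toward the root — whichever node sits in the chain with the
deeper leader jumps to that leader's parent — and needs O(log n) jumps,
giving an O(n^2 log n) all-pairs matrix instead of the naive O(n^3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .tree_model import IndexedTree, preprocess_distance

__all__ = [
    "HeavyChainIndex",
    "DistanceMatrix",
    "chain_cost",
    "heavy_chain_decomposition",
    "lca",
    "node_distance",
    "distance_matrix",
    "matrices_for_replicates",
]


@dataclass
class HeavyChainIndex:
    """Chain assignment of every node.

    ``chain_leader[u]`` is the rank of the topmost node of ``u``'s chain;
    ``chains`` lists each chain root-ward to leaf-ward.  ``jump_counts``
    accumulates the number of chain jumps performed by :func:`lca` calls,
    for complexity instrumentation.
    """

    chain_leader: np.ndarray
    chains: list
    jump_count: int = 0


def chain_cost(t: IndexedTree, chain: Sequence[int]) -> int:
    """Sum of per-node descendant counts over a chain (its decomposition cost)."""
    return int(sum(int(t.descendants[v]) for v in chain))


def heavy_chain_decomposition(t: IndexedTree) -> HeavyChainIndex:
    """Partition the tree into heavy chains in O(n).

    The root leads the first chain; descent always follows the heaviest
    child (maximum ``descendants``, ties broken toward the first child in
    input order, which fixes a deterministic decomposition among the
    equally valid ones).  Every non-heaviest child becomes the leader of
    its own chain.
    """
    preprocess_distance(t)
    n = t.node_count
    chain_leader = np.zeros(n + 1, dtype=np.int64)
    chains: list[list[int]] = []
    # iterative: stack of chain leaders to start
    leaders = [1]
    while leaders:
        leader = leaders.pop()
        chain = []
        u = leader
        while True:
            chain_leader[u] = leader
            chain.append(u)
            kids = t.children[u]
            if not kids:
                break
            heaviest = kids[0]
            best = t.descendants[heaviest]
            for c in kids[1:]:
                if t.descendants[c] > best:
                    heaviest = c
                    best = t.descendants[c]
            for c in kids:
                if c != heaviest:
                    leaders.append(c)
            u = heaviest
        chains.append(chain)
    return HeavyChainIndex(chain_leader=chain_leader, chains=chains)


def lca(idx: HeavyChainIndex, t: IndexedTree, a: int, b: int) -> int:
    """Lowest common ancestor of ``a`` and ``b`` by chain jumping.

    While the two nodes sit in different chains, the one whose chain leader
    is deeper jumps to that leader's parent (skipping the whole chain
    segment in one step); leaders at equal depth break toward the
    larger-rank leader, either being correct.  Once the chains coincide the
    shallower node is the ancestor.
    """
    leader = idx.chain_leader
    depth = t.depth
    parent = t.parent
    la, lb = leader[a], leader[b]
    while la != lb:
        idx.jump_count += 1
        if depth[la] > depth[lb] or (depth[la] == depth[lb] and la > lb):
            a = parent[la]
            la = leader[a]
        else:
            b = parent[lb]
            lb = leader[b]
    return a if depth[a] <= depth[b] else b


def node_distance(t: IndexedTree, idx: HeavyChainIndex, u: int, v: int) -> float:
    """Path length between ``u`` and ``v`` (sum of branch lengths on the path)."""
    w = lca(idx, t, u, v)
    return float(t.dist_root[u] + t.dist_root[v] - 2.0 * t.dist_root[w])


@dataclass
class DistanceMatrix:
    """Symmetric labeled matrix of path-length distances.

    ``scope`` records whether rows cover all nodes or leaves only; row
    order is the preorder of the source tree, so replicate matrices over a
    shared leaf universe are comparable position-by-position once aligned
    on labels.
    """

    labels: list
    values: np.ndarray
    scope: str = "leaves-only"

    @property
    def n(self) -> int:
        return len(self.labels)

    def by_label(self, a: str, b: str) -> float:
        i = self.labels.index(a)
        j = self.labels.index(b)
        return float(self.values[i, j])

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Return a copy with rows/columns permuted into the given label order."""
        pos = {lab: i for i, lab in enumerate(self.labels)}
        perm = np.array([pos[lab] for lab in labels], dtype=np.int64)
        return DistanceMatrix(labels=list(labels),
                              values=self.values[np.ix_(perm, perm)],
                              scope=self.scope)


def _node_labels(t: IndexedTree, ranks: Sequence[int]) -> list[str]:
    # unnamed internal nodes are addressed by their preorder rank
    return [t.labels[u] if t.labels[u] else str(u) for u in ranks]


def distance_matrix(t: IndexedTree, scope: str = "leaves-only",
                    idx: HeavyChainIndex | None = None) -> DistanceMatrix:
    """All-pairs distance matrix, upper triangle computed and mirrored.

    ``scope="leaves-only"`` gives the patristic matrix (tips only);
    ``scope="all-nodes"`` covers internal nodes too.
    """
    if scope not in ("leaves-only", "all-nodes"):
        raise ValueError(f"unknown scope {scope!r}")
    preprocess_distance(t)
    if idx is None:
        idx = heavy_chain_decomposition(t)
    ranks = t.leaves() if scope == "leaves-only" else list(range(1, t.node_count + 1))
    k = len(ranks)
    dist_root = t.dist_root
    values = np.zeros((k, k), dtype=np.float64)
    for i in range(k):
        u = ranks[i]
        du = dist_root[u]
        row = values[i]
        for j in range(i + 1, k):
            v = ranks[j]
            w = lca(idx, t, u, v)
            row[j] = du + dist_root[v] - 2.0 * dist_root[w]
    values += values.T
    return DistanceMatrix(labels=_node_labels(t, ranks), values=values, scope=scope)


def matrices_for_replicates(trees: Iterable[IndexedTree],
                            scope: str = "leaves-only") -> Iterator[DistanceMatrix]:
    """One distance matrix per replicate tree, in a shared label order.

    The first tree fixes the row/column label order; later matrices are
    permuted to match, so element-wise averaging across replicates is
    positional.  A replicate whose label set differs from the first raises
    ``ValueError``.
    """
    label_order: list[str] | None = None
    for t in trees:
        mat = distance_matrix(t, scope=scope)
        if label_order is None:
            label_order = mat.labels
        elif mat.labels != label_order:
            if set(mat.labels) != set(label_order):
                raise ValueError("replicate trees do not share a label universe")
            mat = mat.reorder(label_order)
        yield mat
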