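"""Random expansion of a phylogeny with clade-constrained taxa.

Each phylogenetically uncertain taxon (PUT) is attached at a random point
inside its most derived consensus clade (MDCC).  The key efficiency idea:
after one preorder preprocessing pass over the original tree ``T0``, every
random choice is made on ``T0``'s arrays alone, with no subtree traversal
per insertion.

Two sampling laws are offered:

*node-based*
    the attachment node ``p`` is drawn uniformly from the contiguous
    preorder-rank interval ``[v_mdcc, v_mdcc + descendants[v_mdcc]]``,
    giving every node of the clade (including its root) the same chance;

*branch-based*
    a position is drawn uniformly along the concatenated branch lengths of
    the clade (total ``sigma``), so long branches are proportionally more
    likely to be split.  The offset ``r`` maps to a cumulative DFS length
    ``delta = sum_lengths[v_mdcc] + r`` and the attachment node is found by
    binary search for the smallest ``sum_lengths[p] >= delta``.

Either way the new leaf is attached via a fresh internal node that bisects
the branch immediately above ``p``, which leaves every path between
pre-existing nodes untouched — the original patristic distances are
invariant under expansion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .errors import SelectionError, TreeValidationError
from .tree_model import (
    IndexedTree,
    PutEntry,
    TreeNode,
    build_indexed_tree,
    preprocess_expansion,
)

__all__ = [
    "ExpansionConfig",
    "InsertionChoice",
    "MutableExpandedTree",
    "select_node_based",
    "select_branch_based",
    "subtree_length_sum",
    "insert_leaf",
    "expand",
    "iter_expand",
]


@dataclass
class ExpansionConfig:
    """Parameters of one expansion run.

    method:
        ``"node"`` (uniform over clade nodes) or ``"branch"`` (proportional
        to branch length).  Default ``"branch"``.
    replicates:
        number *m* of independently expanded copies to produce.
    seed:
        base RNG seed; replicate *i* uses the substream ``(seed, i)`` so
        earlier replicates are unchanged when *m* grows.
    pendant_policy / pendant_length:
        length of the new terminal branch. ``"ultrametric"`` (default)
        extends the pendant so the new tip reaches the deepest tip depth of
        its MDCC subtree; ``"fixed"`` uses ``pendant_length`` (> 0).
    split_policy:
        where the new internal node cuts the attachment branch, for the
        node-based method: ``"midpoint"`` (default) or ``"uniform"``.  The
        branch-based method always uses the offset implied by its own draw.
    """

    method: str = "branch"
    replicates: int = 100
    seed: int = 0
    pendant_policy: str = "ultrametric"
    pendant_length: float | None = None
    split_policy: str = "midpoint"

    def __post_init__(self):
        if self.method not in ("node", "branch"):
            raise ValueError(f"method must be 'node' or 'branch', got {self.method!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.pendant_policy not in ("ultrametric", "fixed"):
            raise ValueError(f"unknown pendant policy {self.pendant_policy!r}")
        if self.pendant_policy == "fixed":
            if self.pendant_length is None or self.pendant_length <= 0:
                raise ValueError("fixed pendant policy requires pendant_length > 0")
        if self.split_policy not in ("midpoint", "uniform"):
            raise ValueError(f"unknown split policy {self.split_policy!r}")


@dataclass
class InsertionChoice:
    """A resolved random insertion point for one PUT.

    ``delta`` and ``within_branch_offset`` are set by the branch-based
    method only; the offset is measured from the parent end of the branch
    above ``insertion_node``.
    """

    put: PutEntry
    insertion_node: int
    delta: float | None = None
    within_branch_offset: float | None = None


def select_node_based(t: IndexedTree, v_mdcc: int, rng: np.random.Generator,
                      put: PutEntry | None = None) -> InsertionChoice:
    """Draw the attachment node uniformly from the MDCC's rank interval.

    The interval ``[v_mdcc, v_mdcc + descendants[v_mdcc]]`` is inclusive at
    both ends: the clade root itself may be chosen, in which case the new
    taxon attaches on the branch above the whole clade.  O(1) per draw.
    """
    lo, hi = t.subtree_interval(v_mdcc)
    p = int(rng.integers(lo, hi + 1))
    return InsertionChoice(put=put, insertion_node=p)


def subtree_length_sum(t: IndexedTree, v_mdcc: int) -> float:
    """Total branch length strictly inside the subtree of ``v_mdcc``, in O(1).

    Because ``sum_lengths`` is the preorder prefix sum of branch lengths
    and the subtree occupies the contiguous rank interval
    ``[v_mdcc, v_mdcc + descendants[v_mdcc]]``, the total is the difference
    of the prefix sums at the interval ends.
    """
    lo, hi = t.subtree_interval(v_mdcc)
    return float(t.sum_lengths[hi] - t.sum_lengths[lo])


def select_branch_based(t: IndexedTree, v_mdcc: int, rng: np.random.Generator | None = None,
                        put: PutEntry | None = None, *, r: float | None = None) -> InsertionChoice:
    """Draw the attachment branch with probability proportional to its length.

    A position ``r`` is drawn uniformly on ``(0, sigma]`` where ``sigma``
    is the clade's total branch length; the cumulative DFS coordinate
    ``delta = sum_lengths[v_mdcc] + r`` identifies the branch above the
    node ``p`` with the smallest ``sum_lengths[p] >= delta``, found by
    binary search over the clade's contiguous rank interval.

    ``r`` may be supplied explicitly (for reproducing a known draw);
    otherwise ``rng`` is required.

    Raises :class:`SelectionError` when the clade has no internal branch
    (``sigma == 0``, i.e. a leaf MDCC): use the node-based method there.
    """
    preprocess_expansion(t)
    sigma = subtree_length_sum(t, v_mdcc)
    if sigma <= 0.0:
        raise SelectionError(
            f"MDCC at rank {v_mdcc} has zero internal branch length; "
            "use the node-based method (or a leaf-branch insertion) instead"
        )
    if r is None:
        if rng is None:
            raise ValueError("either rng or an explicit r is required")
        r = float(rng.uniform(0.0, sigma))
        if r == 0.0:
            r = float(np.finfo(np.float64).tiny)
    elif not (0.0 < r <= sigma):
        raise SelectionError(f"r={r} outside (0, {sigma}]")
    lo, hi = t.subtree_interval(v_mdcc)
    delta = float(t.sum_lengths[lo]) + r
    # smallest rank in (lo, hi] whose prefix sum reaches delta
    offset = int(np.searchsorted(t.sum_lengths[lo + 1:hi + 1], delta, side="left"))
    p = min(lo + 1 + offset, hi)
    within = float(t.branch_length[p] - (t.sum_lengths[p] - delta))
    return InsertionChoice(put=put, insertion_node=p, delta=delta,
                           within_branch_offset=within)


class MutableExpandedTree:
    """A mutable copy of the original tree, addressable by original rank.

    ``by_rank[u]`` is the copied node corresponding to original rank ``u``;
    inserted nodes never enter this table, faithful to the design in which
    insertion targets are always original-tree nodes.
    """

    def __init__(self, t0: IndexedTree):
        self.t0 = t0
        self.root = t0.to_tree_node()
        nodes = list(self.root.preorder())  # same order as t0's ranks
        self.by_rank: list[TreeNode | None] = [None] + nodes
        self.taken_names = {t0.labels[u] for u in t0.leaves()}

    def depth_of(self, node: TreeNode) -> float:
        d = 0.0
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        return d

    def to_indexed(self, **kwargs) -> IndexedTree:
        return build_indexed_tree(self.root, **kwargs)


def _max_tip_depth(t0: IndexedTree, v_mdcc: int) -> float:
    lo, hi = t0.subtree_interval(v_mdcc)
    return max(float(t0.dist_root[u]) for u in range(lo, hi + 1) if t0.is_leaf(u))


def insert_leaf(copy: MutableExpandedTree, choice: InsertionChoice, name: str,
                cfg: ExpansionConfig, rng: np.random.Generator | None = None) -> TreeNode:
    """Attach a new leaf above ``choice.insertion_node`` in the copied tree.

    A fresh internal node ``w`` bisects the branch *currently* immediately
    above the attachment node ``p`` (so repeated insertions at the same
    ``p`` nest below one another); ``w`` adopts ``p``'s parent and holds
    ``{p, new leaf}``.  The two halves of the cut branch sum to its length,
    which keeps all pre-existing pairwise path lengths unchanged.  When
    ``p`` is the current root, ``w`` becomes the new root with a
    zero-length stem down to the old root.

    Returns the new leaf node.
    """
    if name in copy.taken_names:
        raise TreeValidationError(f"species name {name!r} collides with an existing leaf")
    p_rank = choice.insertion_node
    p_node = copy.by_rank[p_rank]
    parent = p_node.parent
    w = TreeNode(label=None)

    if parent is None:
        # new root above the old one, zero-length stem
        w.add_child(p_node)
        p_node.length = 0.0
        copy.root = w
    else:
        cur_len = p_node.length if p_node.length is not None else 0.0
        if choice.within_branch_offset is not None:
            orig_len = float(copy.t0.branch_length[p_rank])
            frac = choice.within_branch_offset / orig_len if orig_len > 0 else 0.5
        elif cfg.split_policy == "uniform":
            if rng is None:
                raise ValueError("uniform split policy requires an rng")
            frac = float(rng.uniform(0.0, 1.0))
        else:
            frac = 0.5
        idx = parent.children.index(p_node)
        parent.children[idx] = w
        w.parent = parent
        w.length = frac * cur_len
        w.add_child(p_node)
        p_node.length = cur_len - w.length

    if cfg.pendant_policy == "fixed":
        pendant = cfg.pendant_length
    else:
        v_mdcc = choice.put.mdcc_node if choice.put is not None else p_rank
        pendant = max(_max_tip_depth(copy.t0, v_mdcc) - copy.depth_of(w), 0.0)
    leaf = w.add_child(TreeNode(label=name, length=pendant))
    copy.taken_names.add(name)
    return leaf


def iter_expand(t0: IndexedTree, puts: list[PutEntry],
                cfg: ExpansionConfig) -> Iterator[IndexedTree]:
    """Yield ``cfg.replicates`` independently expanded copies of ``t0``.

    Preprocessing of ``t0`` happens exactly once, up front; every random
    insertion-point choice afterwards reads only ``t0``'s arrays.  Each
    replicate draws from its own deterministic RNG substream, so a fixed
    seed yields a bit-identical replicate set regardless of evaluation
    order.
    """
    preprocess_expansion(t0)
    from .tree_model import preprocess_distance  # dist_root needed for pendant depths
    if cfg.pendant_policy == "ultrametric":
        preprocess_distance(t0)
    for entry in puts:
        if entry.mdcc_node is None:
            raise TreeValidationError(
                f"PUT {entry.species_name!r} has an unresolved MDCC; run resolve_mdccs first"
            )
    for i in range(cfg.replicates):
        rng = np.random.default_rng([cfg.seed, i])
        copy = MutableExpandedTree(t0)
        for entry in puts:
            if cfg.method == "node":
                choice = select_node_based(t0, entry.mdcc_node, rng, put=entry)
            elif t0.is_leaf(entry.mdcc_node):
                # a leaf MDCC has no internal branch to weight: the only
                # insertion point is the leaf's own branch
                choice = InsertionChoice(put=entry, insertion_node=entry.mdcc_node)
            else:
                choice = select_branch_based(t0, entry.mdcc_node, rng, put=entry)
            insert_leaf(copy, choice, entry.species_name, cfg, rng)
        yield copy.to_indexed()


def expand(t0: IndexedTree, puts: list[PutEntry], cfg: ExpansionConfig) -> list[IndexedTree]:
    """Materialise all replicates of :func:`iter_expand` as a list."""
    return list(iter_expand(t0, puts, cfg))
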