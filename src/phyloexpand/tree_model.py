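"""Rooted-tree representation with preorder numbering and preprocessing arrays.

Both core algorithms (random clade-constrained insertion and heavy-chain
distance computation) operate on the same indexed view of a rooted tree:
nodes are identified by their DFS *preorder rank* (1..n, root = 1, children
visited in input order), which gives every subtree a contiguous rank
interval ``[u, u + descendants[u]]``.  The preprocessing arrays are:

``descendants[u]``
    number of nodes strictly below ``u``;
``sum_lengths[u]``
    cumulative branch length along the preorder traversal from the root up
    to and including the branch entering ``u`` (root = 0) — a prefix-sum
    vector whose differences give subtree branch-length totals in O(1);
``dist_root[u]``
    path length from the root to ``u``;
``depth[u]``
    edge-count depth of ``u`` (root = 0).

Arrays are 1-indexed (slot 0 unused) so ranks can be used directly as
indices; ``parent[root] == 0`` is the "no parent" sentinel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import TreeFormatError, TreeValidationError

#: sentinel parent rank of the root
NO_PARENT = 0


class TreeNode:
    """Mutable node of a parsed rooted tree (the pre-indexing representation).

    ``length`` is the length of the branch from the parent into this node;
    ``None`` at the root or when the input omitted it.
    """

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label=None, length=None, children=None):
        self.label: str | None = label
        self.length: float | None = length
        self.children: list[TreeNode] = children if children is not None else []
        self.parent: TreeNode | None = None
        for child in self.children:
            child.parent = self

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self):
        """Yield nodes depth-first, children in stored order."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def copy(self) -> "TreeNode":
        """Deep structural copy (labels and lengths shared as immutables)."""
        clone = TreeNode(self.label, self.length)
        stack = [(self, clone)]
        while stack:
            orig, dup = stack.pop()
            for child in orig.children:
                child_dup = dup.add_child(TreeNode(child.label, child.length))
                stack.append((child, child_dup))
        return clone

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r}, length={self.length}, n_children={len(self.children)})"


@dataclass
class IndexedTree:
    """Rooted tree addressed by preorder rank, with preprocessing arrays.

    All per-node arrays have length ``node_count + 1`` and are indexed by
    rank; index 0 is unused.  ``descendants``/``sum_lengths`` are filled by
    :func:`preprocess_expansion`, ``dist_root``/``depth`` by
    :func:`preprocess_distance`; both are idempotent and count their
    effective runs in ``preprocess_runs`` so callers can assert the
    single-preprocessing contract.
    """

    node_count: int
    leaf_count: int
    labels: list
    parent: np.ndarray
    children: list
    branch_length: np.ndarray
    descendants: np.ndarray | None = None
    sum_lengths: np.ndarray | None = None
    dist_root: np.ndarray | None = None
    depth: np.ndarray | None = None
    preprocess_runs: dict = field(default_factory=lambda: {"expansion": 0, "distance": 0})

    def is_leaf(self, u: int) -> bool:
        return not self.children[u]

    @property
    def root(self) -> int:
        return 1

    def leaves(self) -> list[int]:
        """Ranks of all leaf nodes, in preorder."""
        return [u for u in range(1, self.node_count + 1) if not self.children[u]]

    def subtree_interval(self, u: int) -> tuple[int, int]:
        """Inclusive rank interval [u, u + descendants[u]] covering u's subtree."""
        if self.descendants is None:
            raise TreeValidationError("descendants[] not computed; run preprocess_expansion first")
        return u, u + int(self.descendants[u])

    def label_index(self) -> dict:
        """Map each unique non-empty label to its rank.

        Labels that occur more than once are omitted (they cannot address a
        node unambiguously); leaf labels are guaranteed unique at build time.
        """
        seen: dict = {}
        dupes = set()
        for u in range(1, self.node_count + 1):
            lab = self.labels[u]
            if lab:
                if lab in seen:
                    dupes.add(lab)
                else:
                    seen[lab] = u
        for lab in dupes:
            del seen[lab]
        return seen

    def to_tree_node(self) -> TreeNode:
        """Rebuild the mutable nested representation (for editing or writing)."""
        nodes = [None] * (self.node_count + 1)
        for u in range(1, self.node_count + 1):
            length = None if u == self.root else float(self.branch_length[u])
            nodes[u] = TreeNode(self.labels[u], length)
        for u in range(1, self.node_count + 1):
            for c in self.children[u]:
                nodes[u].add_child(nodes[c])
        return nodes[1]


def build_indexed_tree(topology: TreeNode, *, strict_lengths: bool = False,
                       default_length: float = 1.0) -> IndexedTree:
    """Index a parsed rooted tree by DFS preorder and validate it.

    Children are visited in their stored (input) order, so ranks are
    reproducible from the input file.  Missing branch lengths default to
    ``default_length`` with a warning unless ``strict_lengths`` is set.

    Raises
    ------
    TreeFormatError
        on duplicate leaf labels.
    TreeValidationError
        on negative branch lengths, or missing lengths in strict mode.
    """
    order = list(topology.preorder())
    n = len(order)
    rank_of = {id(node): rank for rank, node in enumerate(order, start=1)}

    labels = [None] * (n + 1)
    parent = np.zeros(n + 1, dtype=np.int64)
    children: list = [[] for _ in range(n + 1)]
    branch_length = np.zeros(n + 1, dtype=np.float64)
    missing_lengths = 0

    leaf_labels: set = set()
    leaf_count = 0
    for rank, node in enumerate(order, start=1):
        labels[rank] = node.label
        children[rank] = [rank_of[id(c)] for c in node.children]
        if node.parent is not None:
            parent[rank] = rank_of[id(node.parent)]
            length = node.length
            if length is None:
                missing_lengths += 1
                length = default_length
            elif length < 0:
                raise TreeValidationError(
                    f"negative branch length {length} on branch into node "
                    f"{node.label!r} (rank {rank})"
                )
            branch_length[rank] = length
        if node.is_leaf():
            leaf_count += 1
            if not node.label:
                raise TreeFormatError(f"leaf at rank {rank} has no label")
            if node.label in leaf_labels:
                raise TreeFormatError(f"duplicate leaf label {node.label!r}")
            leaf_labels.add(node.label)

    if missing_lengths:
        if strict_lengths:
            raise TreeValidationError(
                f"{missing_lengths} branch(es) have no length and strict mode is on"
            )
        warnings.warn(
            f"{missing_lengths} branch(es) without length; defaulting to {default_length}",
            stacklevel=2,
        )

    return IndexedTree(
        node_count=n,
        leaf_count=leaf_count,
        labels=labels,
        parent=parent,
        children=children,
        branch_length=branch_length,
    )


def preprocess_expansion(t: IndexedTree) -> IndexedTree:
    """Fill ``descendants[]`` and ``sum_lengths[]`` in one O(n) pass each.

    ``sum_lengths`` is the prefix sum of branch lengths in preorder, so the
    total branch length inside the subtree of ``u`` is
    ``sum_lengths[u + descendants[u]] - sum_lengths[u]``.
    """
    if t.descendants is not None and t.sum_lengths is not None:
        return t
    n = t.node_count
    descendants = np.zeros(n + 1, dtype=np.int64)
    # reverse preorder: every child is processed before its parent
    parent = t.parent
    for u in range(n, 1, -1):
        descendants[parent[u]] += descendants[u] + 1
    sum_lengths = np.zeros(n + 1, dtype=np.float64)
    np.cumsum(t.branch_length[1:], out=sum_lengths[1:])
    t.descendants = descendants
    t.sum_lengths = sum_lengths
    t.preprocess_runs["expansion"] += 1
    return t


def preprocess_distance(t: IndexedTree) -> IndexedTree:
    """Fill ``dist_root[]`` and ``depth[]`` (and ``descendants[]`` if absent)."""
    if t.dist_root is not None and t.depth is not None:
        return t
    n = t.node_count
    dist_root = np.zeros(n + 1, dtype=np.float64)
    depth = np.zeros(n + 1, dtype=np.int64)
    parent = t.parent
    for u in range(2, n + 1):  # preorder: parent rank < child rank
        p = parent[u]
        dist_root[u] = dist_root[p] + t.branch_length[u]
        depth[u] = depth[p] + 1
    t.dist_root = dist_root
    t.depth = depth
    if t.descendants is None:
        descendants = np.zeros(n + 1, dtype=np.int64)
        for u in range(n, 1, -1):
            descendants[parent[u]] += descendants[u] + 1
        t.descendants = descendants
    t.preprocess_runs["distance"] += 1
    return t


@dataclass
class PutEntry:
    """One species to insert: its name, MDCC label, and (once bound) MDCC rank."""

    species_name: str
    mdcc_label: str
    mdcc_node: int | None = None
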