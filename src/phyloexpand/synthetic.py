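"""Reference fixtures and random instance generators.

Everything the test suite needs is generated here, in memory: a small
13-node reference tree with unit branch lengths whose per-node quantities
are easy to verify by hand, its 23-node expanded counterpart, and random
binary trees with configurable branch-length laws plus matching PUT lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .newick_io import PutFile, auto_label_internal, read_newick
from .tree_model import IndexedTree, PutEntry, TreeNode, build_indexed_tree

__all__ = [
    "RandomTreeSpec",
    "example_tree",
    "example_expanded_tree",
    "random_tree",
    "random_put_set",
]

# 13-node reference tree: binary, unit branch lengths, every node labeled by
# its preorder rank (root=1; leaves 3,4,6,9,10,12,13).
_EXAMPLE_NEWICK = (
    "((3:1,4:1)2:1,(6:1,((9:1,10:1)8:1,(12:1,13:1)11:1)7:1)5:1)1;"
)

# The same tree after inserting five clade-constrained taxa (16,18,20,22,24):
# each attaches through a fresh internal node (15,17,19,21,23) bisecting the
# branch above original node 10, 9, 12, 4 and 3 respectively.  Unit lengths
# throughout: topology, not metric, is what this fixture exercises.
_EXAMPLE_EXPANDED_NEWICK = (
    "(((3:1,24:1)23:1,(4:1,22:1)21:1)2:1,"
    "(6:1,(((9:1,18:1)17:1,(10:1,16:1)15:1)8:1,((12:1,20:1)19:1,13:1)11:1)7:1)5:1)1;"
)


def example_tree() -> IndexedTree:
    """The 13-node unit-length reference tree (7 leaves)."""
    return build_indexed_tree(read_newick(_EXAMPLE_NEWICK)[0])


def example_expanded_tree() -> IndexedTree:
    """The 23-node expansion of :func:`example_tree` (12 leaves)."""
    return build_indexed_tree(read_newick(_EXAMPLE_EXPANDED_NEWICK)[0])


@dataclass
class RandomTreeSpec:
    """Shape and metric of a random tree instance.

    branch_length_law: ``("unit",)``, ``("uniform", a, b)`` or
    ``("exponential", rate)``.  shape: ``"random"`` (uniform random binary
    splits, Yule-like), ``"caterpillar"`` or ``"balanced"``.
    """

    leaf_count: int
    branch_length_law: tuple = ("unit",)
    shape: str = "random"
    seed: int = 0

    def __post_init__(self):
        if self.leaf_count < 1:
            raise ValueError("leaf_count must be >= 1")
        law = self.branch_length_law
        if law[0] not in ("unit", "uniform", "exponential"):
            raise ValueError(f"unknown branch length law {law!r}")
        if law[0] == "uniform" and not (0 <= law[1] < law[2]):
            raise ValueError("uniform law requires 0 <= a < b")
        if law[0] == "exponential" and law[1] <= 0:
            raise ValueError("exponential law requires rate > 0")
        if self.shape not in ("random", "caterpillar", "balanced"):
            raise ValueError(f"unknown shape {self.shape!r}")


def _draw_length(law: tuple, rng: np.random.Generator) -> float:
    if law[0] == "unit":
        return 1.0
    if law[0] == "uniform":
        return float(rng.uniform(law[1], law[2]))
    return float(rng.exponential(1.0 / law[1]))


def random_tree(spec: RandomTreeSpec) -> IndexedTree:
    """Random rooted binary tree with ``spec.leaf_count`` leaves.

    Leaves are labeled ``t1..tn``; internal nodes are labeled by their
    preorder rank so any clade can serve as an MDCC.  The
    ``random`` shape grows the tree by splitting a uniformly chosen
    existing tip, which produces Yule-like topologies; ``caterpillar``
    and ``balanced`` give the two shape extremes.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.leaf_count
    if n == 1:
        return build_indexed_tree(TreeNode(label="t1"))

    if spec.shape == "caterpillar":
        root = TreeNode()
        cursor = root
        for i in range(1, n):
            cursor.add_child(TreeNode(label=f"t{i}"))
            if i < n - 1:
                cursor = cursor.add_child(TreeNode())
            else:
                cursor.add_child(TreeNode(label=f"t{n}"))
    elif spec.shape == "balanced":
        def split(lo, hi):
            if hi == lo:
                return TreeNode(label=f"t{lo}")
            mid = (lo + hi) // 2
            return TreeNode(children=[split(lo, mid), split(mid + 1, hi)])
        root = split(1, n)
    else:
        tips = [TreeNode(label="t1"), TreeNode(label="t2")]
        root = TreeNode(children=list(tips))
        for i in range(3, n + 1):
            victim = tips[int(rng.integers(len(tips)))]
            # the chosen tip becomes internal, its name moves to a new child
            left = TreeNode(label=victim.label)
            right = TreeNode(label=f"t{i}")
            victim.label = None
            victim.add_child(left)
            victim.add_child(right)
            tips[tips.index(victim)] = left
            tips.append(right)

    for node in root.preorder():
        if node.parent is not None:
            node.length = _draw_length(spec.branch_length_law, rng)
    auto_label_internal(root)
    return build_indexed_tree(root)


def random_put_set(t: IndexedTree, count: int, seed: int = 0) -> PutFile:
    """Random PUT list against ``t``: fresh names, MDCCs drawn among labeled internal nodes.

    Species names ``putN`` never collide with leaves of ``t``; every MDCC
    label resolves against ``t`` by construction.
    """
    rng = np.random.default_rng(seed)
    candidates = [t.labels[u] for u in range(1, t.node_count + 1)
                  if t.children[u] and t.labels[u]]
    if count > 0 and not candidates:
        raise ValueError("tree has no addressable internal node to serve as MDCC")
    leaf_labels = {t.labels[u] for u in t.leaves()}
    put_file = PutFile()
    for i in range(1, count + 1):
        name = f"put{i}"
        while name in leaf_labels:
            name = f"put{i}_{int(rng.integers(1 << 30))}"
        mdcc = candidates[int(rng.integers(len(candidates)))]
        put_file.entries.append(PutEntry(species_name=name, mdcc_label=mdcc))
        put_file.line_numbers.append(i)
    return put_file
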