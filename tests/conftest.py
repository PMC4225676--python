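"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use only the parent/children arrays and direct
walks — never the preorder-interval, prefix-sum or heavy-chain machinery
they are meant to check.
"""

import numpy as np
import pytest

from phyloexpand import synthetic
from phyloexpand.tree_model import IndexedTree


@pytest.fixture
def ref_tree() -> IndexedTree:
    """The 13-node unit-length reference tree."""
    return synthetic.example_tree()


@pytest.fixture
def ref_expanded() -> IndexedTree:
    """Its 23-node expanded counterpart."""
    return synthetic.example_expanded_tree()


def brute_subtree(t: IndexedTree, u: int) -> set:
    """All ranks in the subtree of u (including u), by explicit traversal."""
    out = set()
    stack = [u]
    while stack:
        v = stack.pop()
        out.add(v)
        stack.extend(t.children[v])
    return out


def brute_ancestors(t: IndexedTree, u: int) -> list:
    """Path of ranks from u up to the root."""
    path = [u]
    while t.parent[u] != 0:
        u = int(t.parent[u])
        path.append(u)
    return path


def brute_lca(t: IndexedTree, a: int, b: int) -> int:
    anc_a = brute_ancestors(t, a)
    anc_b = set(brute_ancestors(t, b))
    for x in anc_a:
        if x in anc_b:
            return x
    raise AssertionError("rooted tree must have a common ancestor")


def brute_distance(t: IndexedTree, a: int, b: int) -> float:
    """Path length between a and b by walking both to their meeting point."""
    w = brute_lca(t, a, b)
    d = 0.0
    for x in (a, b):
        while x != w:
            d += float(t.branch_length[x])
            x = int(t.parent[x])
    return d


def brute_subtree_branch_sum(t: IndexedTree, u: int) -> float:
    """Total length of branches strictly inside the subtree of u."""
    return sum(float(t.branch_length[v]) for v in brute_subtree(t, u) if v != u)


def random_trees(count: int, max_leaves: int, seed: int, law=("exponential", 1.0)):
    """A reproducible batch of random trees of varied size and metric."""
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(count):
        leaves = int(rng.integers(2, max_leaves + 1))
        specs.append(synthetic.RandomTreeSpec(
            leaf_count=leaves,
            branch_length_law=law,
            seed=int(rng.integers(2 ** 31)),
        ))
    return [synthetic.random_tree(s) for s in specs]
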