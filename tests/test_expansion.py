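"""Insertion-point sampling laws, leaf attachment semantics, replicate generation."""

import itertools

import numpy as np
import pytest
from scipy import stats

from phyloexpand import (
    ExpansionConfig,
    build_indexed_tree,
    distance_matrix,
    expand,
    heavy_chain_decomposition,
    insert_leaf,
    iter_expand,
    preprocess_expansion,
    resolve_mdccs,
    read_put_file,
    select_branch_based,
    select_node_based,
    subtree_length_sum,
    write_newick,
)
from phyloexpand.distance import chain_cost
from phyloexpand.errors import SelectionError, TreeValidationError
from phyloexpand.expansion import InsertionChoice, MutableExpandedTree
from phyloexpand.tree_model import PutEntry, preprocess_distance

from conftest import brute_subtree_branch_sum, random_trees

REF_PUTS = "16 7\n18 9\n20 11\n22 2\n24 2\n"


class TestNodeBasedSelection:
    def test_interval_for_clade_seven(self, ref_tree):
        preprocess_expansion(ref_tree)
        lo, hi = ref_tree.subtree_interval(7)
        assert (lo, hi) == (7, 13)
        rng = np.random.default_rng(0)
        draws = {select_node_based(ref_tree, 7, rng).insertion_node for _ in range(200)}
        assert draws <= set(range(7, 14))

    def test_leaf_mdcc_always_yields_itself(self, ref_tree):
        preprocess_expansion(ref_tree)
        rng = np.random.default_rng(1)
        assert all(select_node_based(ref_tree, 9, rng).insertion_node == 9
                   for _ in range(20))

    def test_uniform_law(self, ref_tree):
        """Each of the 7 clade nodes is drawn with equal frequency."""
        preprocess_expansion(ref_tree)
        rng = np.random.default_rng(2024)
        counts = np.zeros(7)
        for _ in range(20000):
            counts[select_node_based(ref_tree, 7, rng).insertion_node - 7] += 1
        assert stats.chisquare(counts).pvalue > 0.001


class TestSubtreeLengthSum:
    def test_clade_seven_total(self, ref_tree):
        preprocess_expansion(ref_tree)
        assert subtree_length_sum(ref_tree, 7) == 6.0

    def test_leaf_clade_is_empty(self, ref_tree):
        preprocess_expansion(ref_tree)
        assert subtree_length_sum(ref_tree, 9) == 0.0

    def test_matches_brute_force_on_random_trees(self):
        for t in random_trees(5, 60, seed=21):
            preprocess_expansion(t)
            for u in range(1, t.node_count + 1):
                assert subtree_length_sum(t, u) == pytest.approx(
                    brute_subtree_branch_sum(t, u), rel=1e-12)


class TestBranchBasedSelection:
    def test_known_draw_picks_node_twelve(self, ref_tree):
        choice = select_branch_based(ref_tree, 7, r=4.2)
        assert choice.insertion_node == 12
        assert choice.within_branch_offset == pytest.approx(0.2)

    def test_draw_at_sigma_hits_last_subtree_node(self, ref_tree):
        choice = select_branch_based(ref_tree, 7, r=6.0)
        assert choice.insertion_node == 13

    def test_leaf_mdcc_raises_selection_error(self, ref_tree):
        preprocess_expansion(ref_tree)
        with pytest.raises(SelectionError, match="zero internal branch length"):
            select_branch_based(ref_tree, 9, np.random.default_rng(0))

    def test_length_proportional_law(self):
        """Choice frequency of each branch tracks its relative length."""
        t = build_indexed_tree(
            __import__("phyloexpand").read_newick("((A:4,B:1)N:2,C:3)R;")[0])
        preprocess_expansion(t)
        rng = np.random.default_rng(99)
        counts = {u: 0 for u in range(2, 6)}
        n = 20000
        for _ in range(n):
            counts[select_branch_based(t, 1, rng).insertion_node] += 1
        sigma = subtree_length_sum(t, 1)
        expected = [n * float(t.branch_length[u]) / sigma for u in counts]
        assert stats.chisquare(list(counts.values()), expected).pvalue > 0.001


class TestInsertLeaf:
    def _attach(self, t0, rank, name, cfg=None, offset=None, mdcc=None):
        cfg = cfg or ExpansionConfig(replicates=1, seed=0)
        copy = MutableExpandedTree(t0)
        put = PutEntry(name, str(mdcc or rank), mdcc_node=mdcc or rank)
        choice = InsertionChoice(put=put, insertion_node=rank,
                                 within_branch_offset=offset)
        insert_leaf(copy, choice, name, cfg)
        return copy

    def test_single_insertion_adds_two_nodes_one_leaf(self, ref_tree):
        preprocess_expansion(ref_tree)
        preprocess_distance(ref_tree)
        t1 = self._attach(ref_tree, 10, "16", mdcc=7).to_indexed()
        assert t1.node_count == ref_tree.node_count + 2
        assert t1.leaf_count == ref_tree.leaf_count + 1

    def test_reference_attachments_reproduce_expanded_topology(self, ref_tree, ref_expanded):
        """Inserting the five reference taxa above nodes 10,9,12,4,3 recreates
        the 23-node expanded tree: same heavy chains, same root-chain cost."""
        preprocess_expansion(ref_tree)
        preprocess_distance(ref_tree)
        copy = MutableExpandedTree(ref_tree)
        cfg = ExpansionConfig(replicates=1, seed=0)
        for name, rank, mdcc in [("16", 10, 7), ("18", 9, 9), ("20", 12, 11),
                                 ("22", 4, 2), ("24", 3, 2)]:
            put = PutEntry(name, str(mdcc), mdcc_node=mdcc)
            insert_leaf(copy, InsertionChoice(put=put, insertion_node=rank), name, cfg)
        t = copy.to_indexed()
        assert (t.node_count, t.leaf_count) == (23, 12)
        idx = heavy_chain_decomposition(t)
        assert len(idx.chains) == 12
        root_chain = next(c for c in idx.chains if c[0] == 1)
        assert chain_cost(t, root_chain) == 56
        # chain partition matches the reference expanded tree's, compared on
        # leaf labels terminating each chain
        idx_ref = heavy_chain_decomposition(ref_expanded)
        ends = sorted(t.labels[c[-1]] for c in idx.chains)
        ends_ref = sorted(ref_expanded.labels[c[-1]] for c in idx_ref.chains)
        assert ends == ends_ref

    def test_original_leaf_distances_unchanged(self, ref_tree):
        preprocess_expansion(ref_tree)
        preprocess_distance(ref_tree)
        before = distance_matrix(ref_tree)
        t1 = self._attach(ref_tree, 8, "newsp", mdcc=7, offset=0.3).to_indexed()
        after = distance_matrix(t1)
        for a, b in itertools.combinations(before.labels, 2):
            assert after.by_label(a, b) == pytest.approx(before.by_label(a, b), rel=1e-12)

    def test_insertion_at_root_creates_new_root(self, ref_tree):
        preprocess_expansion(ref_tree)
        preprocess_distance(ref_tree)
        t1 = self._attach(ref_tree, 1, "out", mdcc=1).to_indexed()
        assert t1.node_count == 15
        # old root now hangs below the new (unlabeled) root on a zero-length stem
        assert t1.labels[1] is None
        assert t1.labels[2] == "1"
        assert t1.branch_length[2] == 0.0

    def test_name_collision_rejected(self, ref_tree):
        preprocess_expansion(ref_tree)
        preprocess_distance(ref_tree)
        with pytest.raises(TreeValidationError, match="collides"):
            self._attach(ref_tree, 10, "9", mdcc=7)

    def test_fixed_pendant_length(self, ref_tree):
        preprocess_expansion(ref_tree)
        cfg = ExpansionConfig(replicates=1, seed=0,
                              pendant_policy="fixed", pendant_length=0.75)
        copy = self._attach(ref_tree, 10, "16", cfg=cfg, mdcc=7)
        leaf = next(n for n in copy.root.preorder() if n.label == "16")
        assert leaf.length == 0.75

    def test_ultrametric_pendant_reaches_clade_tip_depth(self, ref_tree):
        preprocess_expansion(ref_tree)
        preprocess_distance(ref_tree)
        copy = self._attach(ref_tree, 10, "16", mdcc=7)
        leaf = next(n for n in copy.root.preorder() if n.label == "16")
        assert copy.depth_of(leaf) == pytest.approx(4.0)  # deepest tip of clade 7


class TestExpand:
    def test_replicate_counts(self, ref_tree):
        puts = resolve_mdccs(read_put_file(REF_PUTS), ref_tree)
        trees = expand(ref_tree, puts, ExpansionConfig(replicates=3, seed=7))
        assert len(trees) == 3
        assert all((t.node_count, t.leaf_count) == (23, 12) for t in trees)

    def test_leaf_set_is_union_of_originals_and_puts(self, ref_tree):
        puts = resolve_mdccs(read_put_file(REF_PUTS), ref_tree)
        for t in iter_expand(ref_tree, puts, ExpansionConfig(replicates=5, seed=8)):
            leaf_labels = {t.labels[u] for u in t.leaves()}
            assert leaf_labels == {"3", "4", "6", "9", "10", "12", "13",
                                   "16", "18", "20", "22", "24"}

    def test_no_puts_yields_identical_copies(self, ref_tree):
        trees = expand(ref_tree, [], ExpansionConfig(replicates=4, seed=1))
        ref_nwk = write_newick(ref_tree)
        assert [write_newick(t) for t in trees] == [ref_nwk] * 4

    @pytest.mark.parametrize("method", ["node", "branch"])
    def test_fixed_seed_is_bit_identical(self, ref_tree, method):
        puts = resolve_mdccs(read_put_file(REF_PUTS), ref_tree)
        cfg = ExpansionConfig(method=method, replicates=6, seed=123)
        a = [write_newick(t) for t in expand(ref_tree, puts, cfg)]
        b = [write_newick(t) for t in expand(ref_tree, puts, cfg)]
        assert a == b

    def test_different_seeds_differ(self, ref_tree):
        puts = resolve_mdccs(read_put_file(REF_PUTS), ref_tree)
        a = [write_newick(t) for t in
             expand(ref_tree, puts, ExpansionConfig(replicates=6, seed=1))]
        b = [write_newick(t) for t in
             expand(ref_tree, puts, ExpansionConfig(replicates=6, seed=2))]
        assert a != b

    def test_growing_m_preserves_earlier_replicates(self, ref_tree):
        puts = resolve_mdccs(read_put_file(REF_PUTS), ref_tree)
        short = [write_newick(t) for t in
                 expand(ref_tree, puts, ExpansionConfig(replicates=3, seed=5))]
        long = [write_newick(t) for t in
                expand(ref_tree, puts, ExpansionConfig(replicates=6, seed=5))]
        assert long[:3] == short

    def test_preprocessing_runs_once_regardless_of_m(self):
        from phyloexpand import synthetic
        t0 = synthetic.example_tree()
        puts = resolve_mdccs(read_put_file(REF_PUTS), t0)
        expand(t0, puts, ExpansionConfig(replicates=10, seed=0))
        assert t0.preprocess_runs == {"expansion": 1, "distance": 1}

    def test_original_leaf_distances_invariant_across_replicates(self, ref_tree):
        puts = resolve_mdccs(read_put_file(REF_PUTS), ref_tree)
        base = distance_matrix(ref_tree)
        for t in iter_expand(ref_tree, puts, ExpansionConfig(replicates=5, seed=3)):
            mat = distance_matrix(t)
            for a, b in itertools.combinations(base.labels, 2):
                assert mat.by_label(a, b) == pytest.approx(base.by_label(a, b), rel=1e-12)

    def test_unresolved_put_rejected(self, ref_tree):
        with pytest.raises(TreeValidationError, match="unresolved"):
            expand(ref_tree, [PutEntry("x", "7")], ExpansionConfig(replicates=1, seed=0))


class TestExpansionConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"method": "magic"},
        {"replicates": 0},
        {"pendant_policy": "fixed"},
        {"pendant_policy": "fixed", "pendant_length": -1.0},
        {"split_policy": "golden"},
    ])
    def test_bad_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ExpansionConfig(**kwargs)
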