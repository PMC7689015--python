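import io

import dendropy
import numpy as np
import pytest

from genomepair.phylo import (DistanceMatrix, MultipleAlignment,
                              bootstrap_support, jc_distance,
                              neighbor_joining, prune_long_branches,
                              tree_bipartitions, tree_path_distances,
                              trim_alignment)


class TestTrim:
    def test_gapless_alignment_unchanged(self):
        msa = MultipleAlignment(["a", "b"], ["ACGT", "ACGA"])
        out = trim_alignment(msa)
        assert out.rows == msa.rows

    def test_end_column_kept_at_exact_threshold(self):
        """A column with residues in exactly 25% of rows is kept (stripping
        continues only while presence is strictly below the threshold)."""
        msa = MultipleAlignment(
            ["a", "b", "c", "d"],
            ["AACGT", "-ACGT", "-ACGT", "-ACGT"])  # col 0 presence = 25%
        out = trim_alignment(msa, gap_col_frac=0.80)
        assert out.n_columns == 5

    def test_leading_column_below_threshold_stripped(self):
        msa = MultipleAlignment(
            ["a", "b", "c", "d", "e"],
            ["AACGT", "-ACGT", "-ACGT", "-ACGT", "-ACGT"])  # presence 20%
        out = trim_alignment(msa, gap_col_frac=0.80)
        assert out.n_columns == 4

    def test_internal_gappy_column_removed(self):
        msa = MultipleAlignment(
            ["a", "b", "c", "d"],
            ["AC-GT", "AC-GT", "ACAGT", "ACAGT"])  # middle col: 50% gaps
        out = trim_alignment(msa)
        assert out.n_columns == 4

    def test_trimming_idempotent_and_never_longer(self):
        rng = np.random.default_rng(0)
        chars = np.array(list("ACGT-"))
        rows = ["".join(rng.choice(chars, 60)) for _ in range(6)]
        msa = MultipleAlignment([f"t{i}" for i in range(6)], rows)
        once = trim_alignment(msa)
        twice = trim_alignment(once)
        assert once.n_columns <= msa.n_columns
        assert twice.rows == once.rows

    def test_all_columns_removed_is_error(self):
        msa = MultipleAlignment(["a", "b", "c", "d", "e"],
                                ["A----", "-A---", "--A--", "---A-",
                                 "----A"])
        with pytest.raises(ValueError):
            trim_alignment(msa)


class TestJukesCantor:
    def test_identical_rows_zero(self):
        msa = MultipleAlignment(["a", "b"], ["ACGTACGT", "ACGTACGT"])
        assert jc_distance(msa).values[0, 1] == 0.0

    def test_closed_form_at_p_010(self):
        # 1 mismatch in 10 compared sites
        msa = MultipleAlignment(["a", "b"], ["AAAAAAAAAA", "AAAAAAAAAT"])
        d = jc_distance(msa).values[0, 1]
        assert d == pytest.approx(0.10733, abs=5e-6)

    def test_saturated_pair_capped_with_warning(self):
        msa = MultipleAlignment(["a", "b"], ["AAAA", "TTTA"])  # p = 0.75
        with pytest.warns(UserWarning, match="saturated"):
            d = jc_distance(msa, cap=5.0).values[0, 1]
        assert d == 5.0

    def test_pairwise_deletion(self):
        msa = MultipleAlignment(["a", "b"], ["AC--GT", "ACGT-T"])
        # comparable: cols 0,1,5 -> no mismatches
        assert jc_distance(msa).values[0, 1] == 0.0

    def test_no_comparable_sites_is_error(self):
        msa = MultipleAlignment(["a", "b"], ["A--", "-AA"])
        with pytest.raises(ValueError, match="a.*b"):
            jc_distance(msa)

    def test_monotone_in_p(self):
        base = "A" * 100
        last = -1.0
        for k in range(0, 70, 7):
            other = "T" * k + "A" * (100 - k)
            msa = MultipleAlignment(["a", "b"], [base, other])
            d = jc_distance(msa).values[0, 1]
            assert d > last
            last = d


def random_additive_tree(rng, n_taxa):
    """Random topology with branch lengths in [0.1, 1]; returns
    (dendropy tree, taxa, distance matrix)."""
    import random as pyrandom
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        rng=pyrandom.Random(int(rng.integers(2**31))))
    try:
        tree.collapse_basal_bifurcation()
    except (AttributeError, ValueError):
        pass
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            edge.length = float(rng.uniform(0.1, 1.0))
    tree.is_rooted = False
    taxa = sorted(t.label for t in tree.taxon_namespace)
    pdm = tree.phylogenetic_distance_matrix()
    mat = np.zeros((n_taxa, n_taxa))
    tx = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                mat[i, j] = mat[j, i] = pdm.distance(tx[a], tx[b])
    return tree, taxa, mat


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # unrooted tree ((A:1,B:2):1,(C:3,D:4)) -> pairwise path lengths
        D = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], dtype=float)
        dm = DistanceMatrix(["A", "B", "C", "D"], D)
        tree = neighbor_joining(dm)
        assert tree_bipartitions(tree) == {frozenset({"A", "B"})}
        paths = tree_path_distances(tree)
        names = ["A", "B", "C", "D"]
        for i in range(4):
            for j in range(i + 1, 4):
                assert paths[frozenset((names[i], names[j]))] \
                    == pytest.approx(D[i, j], abs=1e-9)

    def test_three_taxon_closed_form(self):
        D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], D))
        paths = tree_path_distances(tree)
        assert paths[frozenset(("A", "B"))] == pytest.approx(4)
        assert paths[frozenset(("A", "C"))] == pytest.approx(6)
        assert paths[frozenset(("B", "C"))] == pytest.approx(8)

    def test_equidistant_matrix_equal_terminal_branches(self):
        D = np.full((4, 4), 2.0)
        np.fill_diagonal(D, 0.0)
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), D))
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert all(v == pytest.approx(1.0) for v in lengths.values())

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(DistanceMatrix(list("ABC"), D))

    def test_random_additive_matrices_recovered(self):
        """NJ consistency on additive matrices: exact topology and path
        lengths (independent oracle: path lengths on the generating
        tree)."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            true_tree, taxa, mat = random_additive_tree(rng, n)
            est = neighbor_joining(DistanceMatrix(taxa, mat))
            assert tree_bipartitions(est) == tree_bipartitions(true_tree)
            paths = tree_path_distances(est)
            for i in range(n):
                for j in range(i + 1, n):
                    assert paths[frozenset((taxa[i], taxa[j]))] \
                        == pytest.approx(mat[i, j], abs=1e-9)

    def test_agrees_with_dendropy_nj(self):
        """Cross-check topology against dendropy's independent NJ."""
        rng = np.random.default_rng(9)
        _, taxa, mat = random_additive_tree(rng, 8)
        mine = neighbor_joining(DistanceMatrix(taxa, mat))
        csv = "," + ",".join(taxa) + "\n"
        for i, t in enumerate(taxa):
            csv += t + "," + ",".join(str(x) for x in mat[i]) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=",")
        ref = pdm.nj_tree()
        assert tree_bipartitions(mine) == tree_bipartitions(ref)


def clean_split_alignment():
    """Alignment whose every variable column supports the same splits:
    {a1,a2} vs {b1,b2} vs {c1,c2}."""
    block_a = "A" * 10
    block_b = "C" * 10
    block_c = "G" * 10
    quiet = "T" * 10
    constant = "T" * 60
    return MultipleAlignment(
        ["a1", "a2", "b1", "b2", "c1", "c2"],
        [block_a + quiet + quiet + constant,
         block_a + quiet + quiet + constant,
         quiet + block_b + quiet + constant,
         quiet + block_b + quiet + constant,
         quiet + quiet + block_c + constant,
         quiet + quiet + block_c + constant])


class TestBootstrap:
    def test_zero_homoplasy_supports_100(self):
        tree = bootstrap_support(clean_split_alignment(), n_reps=50, seed=1)
        supports = [int(n.label) for n in tree.preorder_node_iter()
                    if n.label is not None and not n.is_leaf()]
        assert supports and all(s == 100 for s in supports)

    def test_no_reps_no_supports(self):
        tree = bootstrap_support(clean_split_alignment(), n_reps=0)
        assert all(n.label is None for n in tree.preorder_node_iter()
                   if not n.is_leaf())

    def test_same_seed_same_supports(self):
        rng = np.random.default_rng(3)
        chars = np.array(list("ACGT"))
        rows = ["".join(rng.choice(chars, 80)) for _ in range(5)]
        msa = MultipleAlignment([f"t{i}" for i in range(5)], rows)
        t1 = bootstrap_support(msa, n_reps=30, seed=5)
        t2 = bootstrap_support(msa, n_reps=30, seed=5)
        lab = lambda t: sorted(n.label for n in t.preorder_node_iter()
                               if n.label is not None and not n.is_leaf())
        assert lab(t1) == lab(t2)

    def test_supports_in_range(self):
        rng = np.random.default_rng(4)
        chars = np.array(list("ACGT"))
        rows = ["".join(rng.choice(chars, 60)) for _ in range(6)]
        msa = MultipleAlignment([f"t{i}" for i in range(6)], rows)
        tree = bootstrap_support(msa, n_reps=25, seed=0)
        for n in tree.preorder_node_iter():
            if n.label is not None and not n.is_leaf():
                assert 0 <= int(n.label) <= 100


class TestPruneLongBranches:
    def _balanced_msa(self):
        return clean_split_alignment()

    def test_balanced_tree_nothing_removed(self):
        msa = self._balanced_msa()
        tree = neighbor_joining(jc_distance(msa))
        _, _, removed = prune_long_branches(tree, msa)
        assert removed == []

    def test_outlier_removed_and_tree_rebuilt(self):
        msa = clean_split_alignment()
        # an outlier differing everywhere from everyone
        rows = msa.rows + ["N" * 0 + "T" * 0 + "ACGTAC" * 15]
        out = MultipleAlignment(msa.taxa + ["weird"], rows)
        tree = neighbor_joining(jc_distance(out))
        kept, new_tree, removed = prune_long_branches(tree, out, factor=5.0)
        assert removed == ["weird"]
        assert set(kept.taxa) == set(msa.taxa)
        assert {lf.taxon.label for lf in new_tree.leaf_node_iter()} \
            == set(msa.taxa)

    def test_infinite_factor_removes_nothing(self):
        msa = self._balanced_msa()
        tree = neighbor_joining(jc_distance(msa))
        _, _, removed = prune_long_branches(tree, msa, factor=float("inf"))
        assert removed == []
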