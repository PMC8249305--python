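"""Binary encoding, Dice, UPGMA + bootstrap, cophenetic fit, PCA."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from sloegen.clustering import (
    bootstrap_supports,
    cophenetic_correlation,
    dice_matrix,
    dice_similarity,
    encode_binary,
    pca,
    upgma,
)
from sloegen.core_io import PolyGenotype


def _geno(acc, **calls):
    return PolyGenotype(
        accession_id=acc, calls={l: frozenset(s) for l, s in calls.items()}
    )


class TestEncodeBinary:
    def test_one_column_per_observed_allele(self):
        bm = encode_binary([_geno("A", L={100, 104}), _geno("B", L={104})])
        assert list(bm.data.columns) == [("L", 100), ("L", 104)]
        assert bm.data.loc["A"].tolist() == [1, 1]
        assert bm.data.loc["B"].tolist() == [0, 1]

    def test_merged_s_data_adds_23_columns_68_ones(self, s_as_locus,
                                                   table1_sgenotypes):
        genos = [_geno(sg.accession_id, L={1}) for sg in table1_sgenotypes]
        plain = encode_binary(genos)
        merged = encode_binary(genos, table1_sgenotypes)
        assert merged.data.shape[1] - plain.data.shape[1] == 23
        s_block = merged.data.loc[:, "S"]
        assert int(s_block.to_numpy().sum()) == 68

    def test_without_s_input_matrix_unchanged(self):
        genos = [_geno("A", L={1, 2}), _geno("B", L={2})]
        assert encode_binary(genos).data.equals(encode_binary(genos, None).data)


class TestDice:
    def test_identical_rows(self):
        assert dice_similarity([1, 1, 0], [1, 1, 0]) == 1.0

    def test_disjoint_rows(self):
        assert dice_similarity([1, 0, 0], [0, 1, 1]) == 0.0

    def test_hand_count(self):
        # {a,b,c} vs {b,c,d} -> 2*2/(3+3)
        assert dice_similarity([1, 1, 1, 0], [0, 1, 1, 1]) == pytest.approx(2 / 3)

    def test_empty_pair_raises(self):
        with pytest.raises(ValueError):
            dice_similarity([0, 0], [0, 0])

    def test_matrix_matches_set_formula_on_singleton_locus(self):
        genos = [_geno("A", L={1, 2, 3}), _geno("B", L={2, 3, 4})]
        sim = dice_matrix(encode_binary(genos))
        a, b = {1, 2, 3}, {2, 3, 4}
        assert sim.loc["A", "B"] == pytest.approx(
            2 * len(a & b) / (len(a) + len(b))
        )

    def test_pairwise_deletion_of_missing_loci(self):
        g1 = PolyGenotype("A", calls={"L1": frozenset({1})},
                          missing=frozenset({"L2"}))
        g2 = _geno("B", L1={1}, L2={9})
        sim = dice_matrix(encode_binary([g1, g2]))
        assert sim.loc["A", "B"] == 1.0  # L2 excluded pairwise


class TestUPGMA:
    def test_two_leaves(self):
        d = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["A", "B"], columns=["A", "B"])
        tree = upgma(d)
        assert tree.root.height == pytest.approx(0.2)

    def test_hand_executed_three_leaf_merge(self):
        names = ["A", "B", "C"]
        d = pd.DataFrame(
            [[0, 0.2, 0.6], [0.2, 0, 0.4], [0.6, 0.4, 0]],
            index=names, columns=names,
        )
        tree = upgma(d)
        ab = next(n for n in tree.internal_nodes() if n.leaves == {"A", "B"})
        assert ab.height == pytest.approx(0.1)
        # group-average: d(AB,C) = (0.6+0.4)/2 = 0.5 -> root height 0.25
        assert tree.root.height == pytest.approx(0.25)

    def test_clone_pair_merges_first_at_zero(self):
        names = ["A", "B", "C"]
        d = pd.DataFrame(
            [[0, 0.0, 0.6], [0.0, 0, 0.5], [0.6, 0.5, 0]],
            index=names, columns=names,
        )
        tree = upgma(d)
        heights = tree.merge_heights()
        assert heights[0] == 0.0
        assert {"A", "B"} in [set(n.leaves) for n in tree.internal_nodes()]

    def test_heights_monotone_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            x = rng.random((n, 5))
            d = squareform(
                np.round(
                    np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1)), 6
                ), checks=False
            )
            names = [f"L{i}" for i in range(n)]
            dm = pd.DataFrame(squareform(d), index=names, columns=names)
            heights = upgma(dm).merge_heights()
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_cophenetic_distances_match_scipy_average_linkage(self):
        rng = np.random.default_rng(11)
        x = rng.random((8, 4))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        names = [f"L{i}" for i in range(8)]
        dm = pd.DataFrame(d, index=names, columns=names)
        ours = upgma(dm).cophenetic_matrix().loc[names, names].to_numpy()
        Z = average(squareform(d, checks=False))
        theirs = squareform(cophenet(Z))
        assert np.allclose(ours, theirs, atol=1e-9)

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0, 0.1], [0.3, 0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError):
            upgma(d)


def _panel_with_clone():
    rng = np.random.default_rng(5)
    genos = []
    for i in range(4):
        calls = {f"L{j}": set(rng.choice(range(100, 140, 2), size=3, replace=False))
                 for j in range(5)}
        genos.append(_geno(f"A{i}", **calls))
    clone = PolyGenotype("A0x", calls=dict(genos[0].calls))
    return genos + [clone]


class TestBootstrap:
    def test_duplicated_accessions_get_full_support(self):
        genos = _panel_with_clone()
        bm = encode_binary(genos)
        tree = upgma(1 - dice_matrix(bm))
        supports = bootstrap_supports(bm, tree, n_replicates=50, seed=0)
        assert supports[frozenset({"A0", "A0x"})] == 100.0

    def test_single_replicate_gives_zero_or_hundred(self):
        genos = _panel_with_clone()
        bm = encode_binary(genos)
        tree = upgma(1 - dice_matrix(bm))
        supports = bootstrap_supports(bm, tree, n_replicates=1, seed=3)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_invalid_replicate_count(self):
        genos = _panel_with_clone()
        bm = encode_binary(genos)
        tree = upgma(1 - dice_matrix(bm))
        with pytest.raises(ValueError):
            bootstrap_supports(bm, tree, n_replicates=0)

    def test_planted_bipartition_strongly_supported(self):
        # two groups drawing from disjoint allele pools
        rng = np.random.default_rng(21)
        genos = []
        for i in range(4):
            calls = {f"L{j}": set(rng.choice(range(100, 120, 2), 3, replace=False))
                     for j in range(6)}
            genos.append(_geno(f"P{i}", **calls))
        for i in range(4):
            calls = {f"L{j}": set(rng.choice(range(200, 220, 2), 3, replace=False))
                     for j in range(6)}
            genos.append(_geno(f"Q{i}", **calls))
        bm = encode_binary(genos)
        tree = upgma(1 - dice_matrix(bm))
        supports = bootstrap_supports(bm, tree, n_replicates=200, seed=2)
        clade_p = frozenset(f"P{i}" for i in range(4))
        clade_q = frozenset(f"Q{i}" for i in range(4))
        assert supports[clade_p] >= 95.0
        assert supports[clade_q] >= 95.0

    def test_supports_stable_across_seeds(self):
        genos = _panel_with_clone()
        bm = encode_binary(genos)
        tree1 = upgma(1 - dice_matrix(bm))
        s1 = bootstrap_supports(bm, tree1, n_replicates=400, seed=1)
        tree2 = upgma(1 - dice_matrix(bm))
        s2 = bootstrap_supports(bm, tree2, n_replicates=400, seed=99)
        for clade in s1:
            assert abs(s1[clade] - s2[clade]) < 10.0


class TestCopheneticCorrelation:
    def test_ultrametric_input_gives_r_one(self):
        names = ["A", "B", "C", "D"]
        d = pd.DataFrame(
            [[0, .2, .6, .6], [.2, 0, .6, .6], [.6, .6, 0, .3], [.6, .6, .3, 0]],
            index=names, columns=names,
        )
        tree = upgma(d)
        r, p = cophenetic_correlation(tree, d, n_permutations=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_constant_distances_reported_undefined(self):
        names = ["A", "B", "C"]
        d = pd.DataFrame(0.5 * (1 - np.eye(3)), index=names, columns=names)
        tree = upgma(d)
        r, p = cophenetic_correlation(tree, d, n_permutations=10, seed=0)
        assert np.isnan(r) and p is None

    def test_permutation_p_matches_exhaustive_enumeration_at_n4(self):
        rng = np.random.default_rng(4)
        x = rng.random((4, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        names = ["A", "B", "C", "D"]
        dm = pd.DataFrame(d, index=names, columns=names)
        tree = upgma(dm)
        coph = tree.cophenetic_matrix().loc[names, names].to_numpy()
        iu = np.triu_indices(4, 1)
        obs = np.corrcoef(d[iu], coph[iu])[0, 1]
        hits = sum(
            np.corrcoef(d[iu], coph[np.ix_(perm, perm)][iu])[0, 1] >= obs - 1e-12
            for perm in itertools.permutations(range(4))
        )
        exact_p = hits / 24
        r, p = cophenetic_correlation(tree, dm, n_permutations=4999, seed=8)
        assert r == pytest.approx(obs)
        assert p == pytest.approx(exact_p, abs=0.05)


class TestPCA:
    def _bm(self, n=6, seed=9):
        rng = np.random.default_rng(seed)
        genos = [
            _geno(f"A{i}", **{
                f"L{j}": set(rng.choice(range(100, 130, 2), 3, replace=False))
                for j in range(4)
            })
            for i in range(n)
        ]
        return encode_binary(genos)

    def test_variance_fractions_sum_to_one(self):
        res = pca(self._bm())
        assert res.variance_fraction.sum() == pytest.approx(1.0)

    def test_duplicated_accessions_identical_scores(self):
        genos = [_geno("A", L={1, 2}), _geno("B", L={1, 2}), _geno("C", L={3})]
        res = pca(encode_binary(genos))
        assert np.allclose(res.scores.loc["A"], res.scores.loc["B"])

    def test_two_cluster_matrix_separated_on_first_axis(self):
        genos = (
            [_geno(f"P{i}", L1={1, 2}, L2={5}) for i in range(3)]
            + [_geno(f"Q{i}", L1={8, 9}, L2={7}) for i in range(3)]
        )
        res = pca(encode_binary(genos))
        p_scores = res.scores.loc[[f"P{i}" for i in range(3)], "PC1"]
        q_scores = res.scores.loc[[f"Q{i}" for i in range(3)], "PC1"]
        assert p_scores.max() < q_scores.min() or q_scores.max() < p_scores.min()

    def test_scores_preserve_euclidean_distances(self):
        bm = self._bm()
        X = bm.data.to_numpy(float)
        X = X - X.mean(axis=0)
        res = pca(bm)
        S = res.scores.to_numpy()
        orig = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        proj = np.sqrt(((S[:, None] - S[None]) ** 2).sum(-1))
        assert np.allclose(orig, proj, atol=1e-9)

    def test_degenerate_matrix_rejected(self):
        genos = [_geno("A", L={1}), _geno("B", L={1}), _geno("C", L={1})]
        with pytest.raises(ValueError):
            pca(encode_binary(genos))


class TestNewick:
    def test_newick_parses_and_preserves_leaf_set(self, s_as_locus):
        bm = encode_binary(s_as_locus)
        tree = upgma(1 - dice_matrix(bm))
        t = dendropy.Tree.get(data=tree.newick(), schema="newick")
        leaves = {l.taxon.label for l in t.leaf_node_iter()}
        assert leaves == set(tree.leaf_names)
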