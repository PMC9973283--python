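"""Diversity, PhILR, permutation tests and differential ASV calling."""

import itertools
from io import StringIO

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import glycostrat as g
from glycostrat.community import _faith_pd, _permanova_f


def _aitchison(comp):
    clr = np.log(comp)
    clr = clr - clr.mean(axis=1, keepdims=True)
    return squareform(pdist(clr))


class TestRarefy:
    def test_row_sums_equal_depth(self, small_asv_sim):
        _, rare, _ = small_asv_sim
        assert (rare.sum(axis=1) == 10_000).all()

    def test_sample_at_depth_unchanged(self):
        counts = pd.DataFrame([[3, 4, 3]], index=["s"], columns=list("abc"))
        out = g.rarefy(counts, 10, seed=0)
        pd.testing.assert_frame_equal(out, counts.astype(np.int64))

    def test_shallow_samples_dropped(self):
        counts = pd.DataFrame([[50, 50], [2, 2]], index=["deep", "shallow"],
                              columns=list("ab"))
        out = g.rarefy(counts, 50, seed=0)
        assert list(out.index) == ["deep"]

    def test_all_below_depth_hard_error(self):
        counts = pd.DataFrame([[1, 1]], index=["s"], columns=list("ab"))
        with pytest.raises(ValueError):
            g.rarefy(counts, 100, seed=0)

    def test_fixed_seed_reproducible(self, small_asv_sim):
        sim, rare, _ = small_asv_sim
        again = g.rarefy(sim.table.counts, 10_000, seed=5)
        pd.testing.assert_frame_equal(rare, again)


class TestAlphaDiversity:
    def test_uniform_composition_closed_forms(self):
        tree = g.synthetic.random_bifurcating_tree(list("abcdefgh"), seed=0)
        counts = pd.DataFrame([[5] * 8], index=["s"], columns=list("abcdefgh"))
        a = g.alpha_diversity(counts, tree)
        assert a["shannon"].iloc[0] == pytest.approx(np.log(8))
        assert a["simpson"].iloc[0] == pytest.approx(1 - 8 * (1 / 8) ** 2)
        assert a["observed_asvs"].iloc[0] == 8

    def test_single_asv_sample(self):
        tree = g.synthetic.random_bifurcating_tree(list("ab"), seed=0)
        a = g.alpha_diversity(
            pd.DataFrame([[7, 0]], index=["s"], columns=list("ab")), tree)
        assert a["shannon"].iloc[0] == 0
        assert a["simpson"].iloc[0] == 0
        assert a["observed_asvs"].iloc[0] == 1

    def test_faith_pd_star_tree_root_convention(self):
        tree = skbio.TreeNode.read(StringIO("(A:1,B:1,C:1);"))
        counts = pd.DataFrame([[1, 1, 0]], index=["s"], columns=list("ABC"))
        assert g.alpha_diversity(counts, tree)["faith_pd"].iloc[0] == 2.0

    def test_faith_pd_matches_skbio_on_rooted_tree(self):
        tips = [f"t{i}" for i in range(12)]
        tree = g.synthetic.random_bifurcating_tree(tips, seed=3)
        rng = np.random.default_rng(0)
        counts = (rng.random((5, 12)) < 0.5).astype(int)
        ours = [
            _faith_pd({t for t, c in zip(tips, row) if c}, tree)
            for row in counts if row.sum()
        ]
        keep = counts[counts.sum(axis=1) > 0]
        ref = skbio.diversity.alpha_diversity(
            "faith_pd", keep, taxa=tips, tree=tree).to_numpy()
        assert np.allclose(ours, ref)

    def test_empty_sample_all_missing(self):
        tree = g.synthetic.random_bifurcating_tree(list("ab"), seed=0)
        a = g.alpha_diversity(
            pd.DataFrame([[0, 0]], index=["s"], columns=list("ab")), tree)
        assert a.loc["s"].isna().all()


class TestPhilr:
    def test_equal_composition_all_balances_zero(self):
        tree = g.synthetic.random_bifurcating_tree(list("abcd"), seed=0)
        counts = pd.DataFrame([[10, 10, 10, 10]], index=["s"],
                              columns=list("abcd"))
        coords = g.philr_transform(counts, tree, pseudocount=0)
        assert np.allclose(coords.to_numpy(), 0)

    def test_two_tip_formula(self):
        tree = skbio.TreeNode.read(StringIO("(x:1,y:1):0;"))
        counts = pd.DataFrame([[8, 2]], index=["s"], columns=["x", "y"])
        coords = g.philr_transform(counts, tree, pseudocount=0)
        assert coords.iloc[0, 0] == pytest.approx(np.sqrt(0.5) * np.log(8 / 2))

    def test_isometry_with_aitchison(self):
        """Euclidean distance on balances equals the CLR-based Aitchison
        distance — the defining property of the ILR basis."""
        rng = np.random.default_rng(0)
        tree = g.synthetic.random_bifurcating_tree(
            [f"t{i}" for i in range(15)], seed=2)
        comp = rng.dirichlet(np.ones(15) * 2, size=20)
        counts = pd.DataFrame(comp, columns=[f"t{i}" for i in range(15)])
        coords = g.philr_transform(counts, tree, pseudocount=0)
        d_philr = squareform(pdist(coords.to_numpy()))
        assert np.abs(d_philr - _aitchison(comp)).max() < 1e-8

    def test_nonbinary_tree_rejected_then_resolvable(self):
        tree = skbio.TreeNode.read(StringIO("(a:1,b:1,c:1):0;"))
        counts = pd.DataFrame([[1, 2, 3]], index=["s"], columns=list("abc"))
        with pytest.raises(ValueError, match="binary"):
            g.philr_transform(counts, tree)
        resolved = g.resolve_multifurcations(tree)
        coords = g.philr_transform(counts, resolved)
        assert coords.shape == (1, 2)


class TestPermanova:
    def test_perfect_separation_minimal_p(self):
        # p can only be beaten down to the partition-symmetry floor: label
        # permutations that reproduce the same two-block partition tie F
        d = np.ones((10, 10))
        d[:5, :5] = 0
        d[5:, 5:] = 0
        np.fill_diagonal(d, 0)
        _, p = g.permanova(d, [0] * 5 + [1] * 5, n_perm=999, seed=0)
        assert p < 0.02

    def test_matches_exhaustive_enumeration(self):
        """Pseudo-F and exact p agree with brute force over all label
        permutations of a 6-point instance."""
        rng = np.random.default_rng(4)
        d = squareform(pdist(rng.normal(size=(6, 2))))
        labels = np.array([0, 0, 0, 1, 1, 1])
        f_obs, _ = g.permanova(d, labels, n_perm=99, seed=0)
        d2 = d ** 2
        f_all = [
            _permanova_f(d2, np.array(perm), 6, 2)
            for perm in itertools.permutations(labels)
        ]
        assert f_obs == pytest.approx(f_all[0])
        exact_p = np.mean([f >= f_obs - 1e-12 for f in f_all])
        # exhaustive p for this well-separated-ish instance; permutation p
        # with all perms enumerated must match the plug-in proportion
        _, p_big = g.permanova(d, labels, n_perm=4999, seed=1)
        assert p_big == pytest.approx(exact_p, abs=0.02)

    def test_group_size_validation(self):
        d = np.zeros((4, 4))
        with pytest.raises(ValueError):
            g.permanova(d, [0, 1, 1, 1])
        with pytest.raises(ValueError):
            g.permanova(d, [0, 0, 0, 0])


class TestMantel:
    def test_self_correlation_is_one(self):
        d = squareform(pdist(np.random.default_rng(0).normal(size=(10, 3))))
        r, p = g.mantel(d, d, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_hand_four_by_four(self):
        a = squareform([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = squareform([2.0, 1.0, 3.0, 5.0, 4.0, 6.0])
        r, _ = g.mantel(a, b, n_perm=99, seed=0)
        assert r == pytest.approx(
            stats.pearsonr([1, 2, 3, 4, 5, 6], [2, 1, 3, 5, 4, 6]).statistic)

    def test_mismatched_ids_rejected(self):
        d1 = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        d2 = pd.DataFrame(np.zeros((3, 3)), index=list("abd"), columns=list("abd"))
        with pytest.raises(ValueError, match="mismatched"):
            g.mantel(d1, d2)


class TestProcrustes:
    def test_rotated_copy_has_zero_m2(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        Y = X @ R.T * 2.5 + 1.0
        m2, p = g.procrustes_test(X, Y, n_perm=99, seed=0)
        assert m2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1 / 100)

    def test_independent_configurations_nonsignificant(self):
        rng = np.random.default_rng(1)
        ps = [g.procrustes_test(rng.normal(size=(15, 2)),
                                rng.normal(size=(15, 2)),
                                n_perm=99, seed=s)[1] for s in range(10)]
        assert np.mean(ps) > 0.2  # p roughly uniform, not piled at 0


class TestLdaScores:
    def test_three_classes_two_axes(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(60, 10)))
        scores = g.lda_scores(X, np.repeat([0, 1, 2], 20))
        assert list(scores.columns) == ["LD1", "LD2"]

    def test_separated_classes_give_separation(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (30, 6)), rng.normal(8, 1, (30, 6))])
        scores = g.lda_scores(pd.DataFrame(X), np.repeat([0, 1], 30))
        a, b = scores.iloc[:30, 0], scores.iloc[30:, 0]
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        assert abs(a.mean() - b.mean()) > 5 * pooled

    def test_tiny_class_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(ValueError):
            g.lda_scores(X, [0, 0, 0, 0, 1])


class TestBhAdjust:
    def test_hand_step_up(self):
        assert np.allclose(g.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert g.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.allclose(g.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_stable_under_reordering(self):
        p = np.array([0.001, 0.2, 0.04, 0.9, 0.015])
        q = g.bh_adjust(p)
        perm = [3, 0, 4, 1, 2]
        assert np.allclose(g.bh_adjust(p[perm]), q[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            g.bh_adjust([0.5, 1.2])


class TestDifferentialAsvs:
    def test_planted_set_recovered(self, small_asv_sim):
        sim, rare, lab = small_asv_sim
        res = g.differential_asvs(rare, lab)
        found, planted = set(res.cluster_specific), set(sim.planted_asvs)
        tp = len(found & planted)
        assert tp / len(planted) >= 0.9
        assert (len(found) - tp) / max(len(found), 1) <= 0.1

    def test_log2fc_formula(self):
        assert np.log2((0.02 + 1e-6) / (0.005 + 1e-6)) == pytest.approx(2.0, abs=1e-3)

    def test_invariant_to_column_and_sample_order(self, small_asv_sim):
        _, rare, lab = small_asv_sim
        res1 = g.differential_asvs(rare, lab)
        rng = np.random.default_rng(0)
        cols = rng.permutation(rare.columns)
        rows = rng.permutation(len(rare))
        res2 = g.differential_asvs(rare.iloc[rows][cols],
                                   np.asarray(lab)[rows])
        assert res1.cluster_specific == res2.cluster_specific

    def test_requires_three_clusters(self, small_asv_sim):
        _, rare, lab = small_asv_sim
        with pytest.raises(ValueError, match="3 clusters"):
            g.differential_asvs(rare, np.where(np.asarray(lab) == 2, 0,
                                               np.asarray(lab)))


class TestWilcoxonBackend:
    def test_matches_exact_enumeration_for_small_groups(self):
        """The rank-sum p for tie-free groups of size <= 8 equals brute-force
        enumeration over all group assignments."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=6)
        y = rng.normal(size=5) + 0.5
        p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        pooled = np.concatenate([x, y])
        u_obs = stats.mannwhitneyu(x, y).statistic
        us = []
        for comb in itertools.combinations(range(11), 6):
            xi = pooled[list(comb)]
            yi = np.delete(pooled, list(comb))
            us.append(stats.mannwhitneyu(xi, yi).statistic)
        us = np.asarray(us)
        n1, n2 = 6, 5
        mid = n1 * n2 / 2
        p_exact = np.mean(np.abs(us - mid) >= np.abs(u_obs - mid) - 1e-12)
        assert p_scipy == pytest.approx(p_exact)
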