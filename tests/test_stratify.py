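"""PAM clustering, model selection, stability and center assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.metrics import adjusted_rand_score

import glycostrat as g
from glycostrat.clinical import StratificationMatrix
from glycostrat.stratify import jaccard
from conftest import separable_spec


def _dist(X):
    return squareform(pdist(np.asarray(X, dtype=float)))


def _matrix_from_points(X):
    df = pd.DataFrame(X, index=[f"p{i:03d}" for i in range(len(X))])
    df.columns = [f"v{j}" for j in range(df.shape[1])]
    z = (df - df.mean()) / df.std(ddof=1)
    return StratificationMatrix(values=z, means=df.mean(), sds=df.std(ddof=1))


def brute_force_pam(d, k):
    """Independent oracle: same BUILD, then steepest-descent swap search by
    direct cost recomputation."""
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=0)))]
    nearest = d[medoids[0]].copy()
    while len(medoids) < k:
        red = np.maximum(nearest[None, :] - d, 0).sum(axis=1)
        red[medoids] = -np.inf
        j = int(np.argmax(red))
        medoids.append(j)
        nearest = np.minimum(nearest, d[j])
    current = set(medoids)

    def cost(m):
        return d[sorted(m)].min(axis=0).sum()

    while True:
        c0 = cost(current)
        best, best_swap = -1e-12, None
        for m in sorted(current):
            for x in range(n):
                if x in current:
                    continue
                dc = cost(current - {m} | {x}) - c0
                if dc < best:
                    best, best_swap = dc, (m, x)
        if best_swap is None:
            return cost(current)
        m, x = best_swap
        current = current - {m} | {x}


class TestPam:
    def test_perfectly_separated_pairs(self):
        d = _dist(np.array([[0.0], [0.1], [10.0], [10.1]]))
        medoids, labels, _ = g.pam_cluster(d, 2)
        assert labels[0] == labels[1] != labels[2] == labels[3]

    def test_k_equals_n_minus_1_cost_is_min_pairwise(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(7, 3))
        d = _dist(X)
        _, _, cost = g.pam_cluster(d, 6)
        assert cost == pytest.approx(d[np.triu_indices(7, 1)].min())

    def test_matches_brute_force_swap_descent(self):
        """The vectorized SWAP must equal direct-recomputation steepest
        descent on every instance."""
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(5, 9))
            k = int(rng.integers(2, 4))
            d = _dist(rng.normal(size=(n, 2)))
            _, _, cost = g.pam_cluster(d, k)
            assert cost == pytest.approx(brute_force_pam(d, k))

    def test_cost_never_below_global_optimum(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n, k = 7, 3
            d = _dist(rng.normal(size=(n, 2)))
            _, _, cost = g.pam_cluster(d, k)
            opt = min(d[list(M)].min(axis=0).sum()
                      for M in itertools.combinations(range(n), k))
            assert cost >= opt - 1e-9

    def test_invalid_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            g.pam_cluster(d, 2)
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            g.pam_cluster(d, 2)


class TestSilhouette:
    def test_ideal_two_block_structure(self):
        d = np.ones((6, 6))
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        assert g.silhouette_mean(d, [0, 0, 0, 1, 1, 1]) == pytest.approx(1.0)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(1)
        d = _dist(rng.random((100, 5)))
        s = g.silhouette_mean(d, rng.integers(0, 3, 100))
        assert abs(s) < 0.1

    def test_singleton_contributes_zero(self):
        from sklearn.metrics import silhouette_samples
        d = _dist(np.array([[0.0], [0.1], [5.0]]))
        vals = silhouette_samples(d, np.array([0, 0, 1]), metric="precomputed")
        assert vals[2] == 0.0

    def test_single_cluster_rejected(self):
        d = _dist(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError):
            g.silhouette_mean(d, [0] * 5)


class TestSelectK:
    def test_two_separated_gaussians_select_two(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (30, 4)), rng.normal(8, 1, (30, 4))])
        res = g.select_k(_matrix_from_points(X), (2, 6))
        assert res.k == 2

    def test_three_separated_gaussians_select_three(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(c, 1, (25, 4)) for c in (0, 10, 20)])
        res = g.select_k(_matrix_from_points(X), (2, 6))
        assert res.k == 3
        assert res.silhouette == max(res.silhouette_by_k.values())

    def test_unstructured_data_weak_silhouette(self):
        rng = np.random.default_rng(3)
        res = g.select_k(_matrix_from_points(rng.normal(size=(80, 5))), (2, 6))
        assert res.silhouette < 0.25

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(c, 1, (20, 3)) for c in (0, 6, 12)])
        m1 = _matrix_from_points(X)
        perm = rng.permutation(len(X))
        m2 = StratificationMatrix(values=m1.values.iloc[perm],
                                  means=m1.means, sds=m1.sds)
        r1 = g.select_k(m1, (2, 5))
        r2 = g.select_k(m2, (2, 5))
        assert r1.k == r2.k
        joined = pd.concat([r1.labels.rename("a"), r2.labels.rename("b")],
                           axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == pytest.approx(1.0)


class TestBootstrapStability:
    def test_jaccard_identity(self):
        assert jaccard({1, 2, 3}, {1, 2, 3}) == 1.0
        assert jaccard({1, 2}, {3, 4}) == 0.0

    def test_separated_clusters_are_stable(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(c, 0.5, (25, 3)) for c in (0, 6, 12)])
        means = g.bootstrap_stability(_matrix_from_points(X), 3, B=30, seed=0)
        assert (means > 0.95).all()

    def test_pure_noise_is_unstable(self):
        rng = np.random.default_rng(2)
        means = g.bootstrap_stability(
            _matrix_from_points(rng.normal(size=(60, 4))), 3, B=30, seed=0)
        assert means.min() < 0.6

    def test_minimum_replicates_enforced(self):
        m = _matrix_from_points(np.random.default_rng(0).normal(size=(20, 2)))
        with pytest.raises(ValueError):
            g.bootstrap_stability(m, 2, B=5)


class TestAssignToCenters:
    def _centers(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(c, 1, (25, 14)) for c in (5, 10, 15)])
        df = pd.DataFrame(X, columns=list(g.SHARED_VARIABLES),
                          index=[f"p{i}" for i in range(len(X))])
        z = (df - df.mean()) / df.std(ddof=1)
        m = StratificationMatrix(values=z, means=df.mean(), sds=df.std(ddof=1))
        labels = pd.Series(np.repeat([0, 1, 2], 25), index=df.index)
        return g.compute_centers(m, labels), m

    def test_row_equal_to_center_assigned_there(self):
        centers, m = self._centers()
        raw = centers.medians * centers.sds + centers.means
        table = g.ClinicalTable(raw.copy().set_axis(["a", "b", "c"], axis=0))
        labels, excl = g.assign_to_centers(table, centers)
        assert labels.tolist() == [0, 1, 2] and not excl

    def test_equidistant_tie_goes_to_lowest_cluster(self):
        centers, _ = self._centers()
        mid = (centers.medians.iloc[0] + centers.medians.iloc[1]) / 2
        raw = (mid * centers.sds + centers.means).to_frame().T
        raw.index = ["tie"]
        labels, _ = g.assign_to_centers(g.ClinicalTable(raw), centers)
        assert labels.loc["tie"] == 0

    def test_synthetic_test_cohort_recovered(self):
        clin = g.simulate_clinical(separable_spec(21, n=(40, 30, 14)))
        m = g.build_stratification_matrix(clin, k_max=3)
        res = g.select_k(m, (2, 4))
        labels, _ = g.relabel_by_severity(
            res.labels, g.derive_metrics(clin)["glucose_auc"])
        centers = g.compute_centers(m, labels)
        test = g.simulate_clinical(separable_spec(22, n=(20, 15, 8)))
        assigned, _ = g.assign_to_centers(test, centers)
        truth = test.data.loc[assigned.index, "true_cluster"]
        assert adjusted_rand_score(truth, assigned) > 0.85

    def test_variable_mismatch_lists_names(self):
        centers, _ = self._centers()
        df = pd.DataFrame({"hba1c": [5.0]}, index=["x"])
        with pytest.raises(ValueError, match="glucose_0"):
            g.assign_to_centers(g.ClinicalTable(df), centers)


class TestRelabelBySeverity:
    def test_orders_clusters_by_glucose_auc(self):
        labels = pd.Series([2, 2, 0, 0, 1, 1], index=list("abcdef"))
        auc = pd.Series([900, 910, 2000, 2100, 1400, 1500], index=list("abcdef"))
        new, mapping = g.relabel_by_severity(labels, auc)
        assert new.tolist() == [0, 0, 2, 2, 1, 1]
        assert mapping == {2: 0, 1: 1, 0: 2}
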