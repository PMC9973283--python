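"""K-medoids stratification: PAM, silhouette model selection, bootstrap
stability and out-of-sample assignment.

PAM here is the classic partitioning-around-medoids algorithm: a greedy
BUILD phase seeds k medoids, then the SWAP phase exchanges a medoid with a
non-medoid whenever that lowers the total within-cluster distance, until no
single swap improves the objective.  The algorithm is deterministic; ties
are broken toward the lowest point index.

Cluster stability follows the bootstrap-Jaccard scheme of clusterboot:
recluster resampled data and score each original cluster by its mean
Jaccard similarity with the best-matching bootstrap cluster; means above
0.7 are conventionally called stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.metrics import silhouette_samples

from .clinical import StratificationMatrix
from .io import ClinicalTable, SHARED_VARIABLES, logger

STABILITY_THRESHOLD = 0.7
_MAX_SWAP_ITER = 500


def _check_distance_matrix(dist: np.ndarray) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


def pam_cluster(dist: np.ndarray, k: int, seed: int = 0
                ) -> tuple[np.ndarray, np.ndarray, float]:
    """PAM (BUILD + SWAP) on a precomputed distance matrix.

    Returns ``(medoid_indices, labels, total_cost)``.  The procedure is
    deterministic; ``seed`` is accepted for interface uniformity only.
    Every point is assigned to its nearest medoid, each medoid to itself.
    """
    d = _check_distance_matrix(dist)
    n = d.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n, got k={k}, n={n}")

    # BUILD: first medoid minimizes total distance; each next maximizes
    # the reduction in cost.  argmin/argmax take the first (lowest) index.
    medoids = [int(np.argmin(d.sum(axis=0)))]
    nearest_d = d[medoids[0]].copy()
    while len(medoids) < k:
        reduction = np.maximum(nearest_d[None, :] - d, 0).sum(axis=1)
        reduction[medoids] = -np.inf
        j = int(np.argmax(reduction))
        medoids.append(j)
        nearest_d = np.minimum(nearest_d, d[j])

    medoids = np.array(medoids)
    for _ in range(_MAX_SWAP_ITER):
        dm = d[medoids]                           # k x n
        order = np.argsort(dm, axis=0, kind="stable")
        nearest_i = order[0]                      # medoid slot per point
        nearest_d = dm[nearest_i, np.arange(n)]
        second_d = dm[order[1], np.arange(n)]

        is_medoid = np.zeros(n, dtype=bool)
        is_medoid[medoids] = True
        cand = np.flatnonzero(~is_medoid)
        dc = d[cand]                              # c x n
        a = np.minimum(dc, nearest_d[None, :]) - nearest_d[None, :]
        b = np.minimum(dc, second_d[None, :]) - nearest_d[None, :]
        onehot = np.zeros((n, len(medoids)))
        onehot[np.arange(n), nearest_i] = 1.0
        delta = a.sum(axis=1, keepdims=True) + (b - a) @ onehot

        best = int(np.argmin(delta))
        ci, mi = divmod(best, len(medoids))
        if delta[ci, mi] >= -1e-12:
            break
        medoids[mi] = cand[ci]
    else:  # pragma: no cover - safety valve
        logger.warning("PAM SWAP did not converge in %d iterations",
                       _MAX_SWAP_ITER)

    medoids = np.sort(medoids)
    labels = np.argmin(d[medoids], axis=0)
    labels[medoids] = np.arange(len(medoids))
    total_cost = float(d[medoids, :].min(axis=0).sum())
    return medoids, labels, total_cost


def silhouette_mean(dist: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width; singleton clusters contribute 0."""
    d = _check_distance_matrix(dist)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_samples(d, labels, metric="precomputed").mean())


@dataclass
class StratificationResult:
    """Selected PAM model with its silhouette profile and stability."""

    k: int
    medoid_ids: list[str]
    labels: pd.Series                         # participant -> cluster index
    silhouette_by_k: dict[int, float]
    total_cost: float
    jaccard_stability: np.ndarray | None = None

    @property
    def silhouette(self) -> float:
        return self.silhouette_by_k[self.k]


def select_k(matrix: StratificationMatrix, k_range: tuple[int, int] = (2, 20),
             seed: int = 0) -> StratificationResult:
    """PAM across ``k_range``; keep the k with maximal mean silhouette.

    Distances are Euclidean on the standardized variables.  Silhouette ties
    go to the smallest k.  A winning silhouette below 0.25 is logged as
    weak structure.
    """
    X = matrix.values.to_numpy()
    n = X.shape[0]
    lo, hi = k_range
    if lo < 2 or hi >= n:
        raise ValueError(f"k_range {k_range} outside [2, n-1] for n={n}")
    d = squareform(pdist(X, metric="euclidean"))
    profile: dict[int, float] = {}
    models = {}
    for k in range(lo, hi + 1):
        medoids, labels, cost = pam_cluster(d, k, seed)
        profile[k] = silhouette_mean(d, labels)
        models[k] = (medoids, labels, cost)
    best_k = max(profile, key=lambda k: (profile[k], -k))
    medoids, labels, cost = models[best_k]
    if profile[best_k] < 0.25:
        logger.warning("weak cluster structure: max silhouette %.3f",
                       profile[best_k])
    ids = matrix.values.index
    return StratificationResult(
        k=best_k,
        medoid_ids=[str(ids[m]) for m in medoids],
        labels=pd.Series(labels, index=ids, name="cluster"),
        silhouette_by_k=profile,
        total_cost=cost,
    )


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def bootstrap_stability(matrix: StratificationMatrix, k: int, B: int = 100,
                        seed: int = 0) -> np.ndarray:
    """Mean bootstrap Jaccard similarity per original cluster.

    Each bootstrap resamples participants with replacement, reclusters with
    PAM(k), and matches every original cluster to its most similar
    bootstrap cluster on the participants present in the resample.
    """
    if B < 20:
        raise ValueError("need at least 20 bootstrap replicates")
    X = matrix.values.to_numpy()
    n = X.shape[0]
    d = squareform(pdist(X, metric="euclidean"))
    _, orig_labels, _ = pam_cluster(d, k, seed)
    orig_sets = [set(np.flatnonzero(orig_labels == c)) for c in range(k)]

    rng = np.random.default_rng(seed)
    sums = np.zeros(k)
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        if len(np.unique(idx)) < k:
            logger.warning("degenerate bootstrap resample redrawn")
            continue
        sub = d[np.ix_(idx, idx)]
        _, boot_labels, _ = pam_cluster(sub, k, seed)
        present = set(idx.tolist())
        boot_sets = [
            {int(idx[i]) for i in np.flatnonzero(boot_labels == c)}
            for c in range(k)
        ]
        for c, orig in enumerate(orig_sets):
            restricted = orig & present
            sums[c] += max(jaccard(restricted, bs) for bs in boot_sets)
        b += 1
    means = sums / B
    for c, m in enumerate(means):
        logger.info("cluster %d bootstrap Jaccard %.3f (%s)", c, m,
                    "stable" if m > STABILITY_THRESHOLD else "unstable")
    return means


@dataclass
class ClusterCenters:
    """Per-cluster medians on the discovery z-scale plus that scale."""

    variables: tuple[str, ...]
    medians: pd.DataFrame                     # clusters x variables
    means: pd.Series                          # discovery scaling
    sds: pd.Series


def compute_centers(matrix: StratificationMatrix, labels: pd.Series,
                    variables: tuple[str, ...] = SHARED_VARIABLES
                    ) -> ClusterCenters:
    """Median standardized profile of each cluster on the shared variables."""
    z = matrix.values[list(variables)]
    med = z.groupby(labels.reindex(z.index)).median()
    med.index.name = "cluster"
    return ClusterCenters(
        variables=tuple(variables),
        medians=med,
        means=matrix.means[list(variables)],
        sds=matrix.sds[list(variables)],
    )


def assign_to_centers(test_table: ClinicalTable, centers: ClusterCenters,
                      outlier_z: float = 5.0, standardized: bool = True
                      ) -> tuple[pd.Series, dict[str, str]]:
    """Nearest-center assignment of a testing cohort.

    Test participants are standardized with the DISCOVERY scaling
    parameters; rows with missing variables or any |z| >= ``outlier_z`` are
    excluded.  Ties go to the lowest cluster index.  With
    ``standardized=False`` distances are taken on the raw variable scale.
    """
    missing = [v for v in centers.variables if v not in test_table.data.columns]
    if missing:
        raise ValueError(f"test cohort lacks variables: {missing}")
    df = test_table.data[list(centers.variables)].astype(float)
    excluded: dict[str, str] = {}
    complete = df.dropna()
    for pid in df.index.difference(complete.index):
        excluded[str(pid)] = "missing"
    z = (complete - centers.means) / centers.sds
    out = z.abs().ge(outlier_z).any(axis=1)
    for pid in z.index[out]:
        excluded[str(pid)] = "outlier"
    z = z.loc[~out]
    if standardized:
        dists = cdist(z.to_numpy(), centers.medians.to_numpy())
    else:
        raw_centers = centers.medians * centers.sds + centers.means
        dists = cdist(complete.loc[z.index].to_numpy(), raw_centers.to_numpy())
    labels = pd.Series(np.argmin(dists, axis=1), index=z.index, name="cluster")
    if excluded:
        logger.info("excluded %d test participants", len(excluded))
    return labels, excluded


def relabel_by_severity(labels: pd.Series, glucose_auc: pd.Series
                        ) -> tuple[pd.Series, dict[int, int]]:
    """Renumber clusters by ascending mean glucose AUC of their members.

    Fixes cluster semantics deterministically: cluster 0 is the best
    glycemia, the last cluster the worst.  Returns the relabeled series and
    the old->new mapping.
    """
    means = glucose_auc.groupby(labels.reindex(glucose_auc.index)).mean()
    order = means.sort_values(kind="stable").index
    mapping = {int(old): new for new, old in enumerate(order)}
    return labels.map(mapping).rename("cluster"), mapping
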