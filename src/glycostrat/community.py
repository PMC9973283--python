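"""Microbiome community structure: rarefaction, diversity, the phylogenetic
isometric log-ratio (PhILR) ordination, global permutation tests, and
cluster-specific ASV identification.

The PhILR transform maps a composition onto one balance per internal node
of a rooted binary phylogeny.  For a node whose left clade has r tips (set
L) and right clade s tips (set R),

    balance = sqrt(r*s / (r+s)) * ln( gmean(x_L) / gmean(x_R) )

on the zero-replaced, closed composition.  The balances form an orthonormal
ILR basis, so Euclidean distance between balance vectors equals the
Aitchison distance between the compositions — the property ordination and
PERMANOVA rely on.

Differential ASVs between two clusters are those with a Benjamini-Hochberg
FDR below ``fdr_alpha`` (Wilcoxon rank-sum on relative abundances, adjusted
within the contrast) together with |log2 fold change| above ``log2fc_min``;
the cluster-specific feature set is the union over the three pairwise
contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy import stats
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from .io import AsvTable, logger

LOG2FC_EPS = 1e-6


# ---------------------------------------------------------------------------
# rarefaction and alpha diversity


def rarefy(counts: pd.DataFrame, depth: int, seed: int = 0) -> pd.DataFrame:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (logged).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    totals = counts.sum(axis=1)
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"all samples below rarefaction depth {depth}")
    if (~keep).any():
        logger.warning("dropping %d samples below depth %d", int((~keep).sum()),
                       depth)
    rng = np.random.default_rng(seed)
    sub = counts.loc[keep]
    out = np.empty(sub.shape, dtype=np.int64)
    arr = sub.to_numpy().astype(np.int64)
    for i in range(arr.shape[0]):
        out[i] = rng.multivariate_hypergeometric(arr[i], depth)
    return pd.DataFrame(out, index=sub.index, columns=sub.columns)


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("cannot close empty samples")
    return counts.div(totals, axis=0)


def _faith_pd(present: set[str], tree: skbio.TreeNode) -> float:
    """Branch-length sum of the minimal root-spanning subtree of ``present``.

    The root's own edge is excluded.  Computed bottom-up: an edge counts
    when its subtree contains at least one present tip.
    """
    if not present:
        return np.nan
    total = 0.0
    has_present: dict[int, bool] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            hit = node.name in present
        else:
            hit = any(has_present[id(c)] for c in node.children)
        has_present[id(node)] = hit
        if hit and node.parent is not None and node.length is not None:
            total += node.length
    return total


def alpha_diversity(counts: pd.DataFrame, tree: skbio.TreeNode) -> pd.DataFrame:
    """Shannon (nats), Simpson (1 - sum p^2), observed ASVs and Faith's PD.

    Faith's PD sums branch lengths of the minimal subtree connecting the
    present tips to the root, excluding the root's own edge.
    """
    arr = counts.to_numpy(dtype=float)
    empty = arr.sum(axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = arr / arr.sum(axis=1, keepdims=True)
        logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
    shannon = -(p * logp).sum(axis=1)
    simpson = 1.0 - (p ** 2).sum(axis=1)
    observed = (arr > 0).sum(axis=1).astype(float)

    faith = np.array([
        _faith_pd(set(counts.columns[row > 0]), tree)
        for row in arr
    ])
    out = pd.DataFrame(
        {"shannon": shannon, "simpson": simpson, "observed_asvs": observed,
         "faith_pd": faith},
        index=counts.index,
    )
    out[empty] = np.nan
    return out


# ---------------------------------------------------------------------------
# PhILR


def resolve_multifurcations(tree: skbio.TreeNode) -> skbio.TreeNode:
    """Binary copy of ``tree``: multifurcations are expanded left-branching
    with zero-length internal edges, children taken in tip lexicographic
    order."""
    tree = tree.copy()
    for node in list(tree.traverse(include_self=True)):
        while len(node.children) > 2:
            kids = sorted(node.children, key=lambda c: min(t.name for t in c.tips(include_self=True)))
            a, b = kids[0], kids[1]
            node.remove(a)
            node.remove(b)
            merged = skbio.TreeNode(children=[a, b])
            merged.length = 0.0
            node.append(merged)
    return tree


def philr_transform(counts: pd.DataFrame, tree: skbio.TreeNode,
                    pseudocount: float = 1.0) -> pd.DataFrame:
    """Balance coordinates of each sample on a rooted binary phylogeny.

    Zeros are handled by adding ``pseudocount`` to every count before
    closure.  Coordinates are ordered by preorder traversal of the internal
    nodes; column ``n<i>`` belongs to the i-th internal node visited.
    """
    tips = {t.name for t in tree.tips()}
    missing = set(counts.columns) - tips
    if missing:
        raise ValueError(f"{len(missing)} ASVs not in tree")
    sub = tree.shear(set(counts.columns)) if tips - set(counts.columns) else tree
    for node in sub.non_tips(include_self=True):
        if len(node.children) != 2:
            raise ValueError("tree must be binary for the PhILR transform; "
                             "resolve multifurcations first")

    comp = counts.to_numpy(dtype=float) + pseudocount
    comp = comp / comp.sum(axis=1, keepdims=True)
    logx = np.log(comp)
    col_of = {name: j for j, name in enumerate(counts.columns)}

    names, cols = [], []
    for i, node in enumerate(sub.preorder(include_self=True)):
        if node.is_tip():
            continue
        left, right = node.children
        li = [col_of[t.name] for t in left.tips(include_self=True)]
        ri = [col_of[t.name] for t in right.tips(include_self=True)]
        r, s = len(li), len(ri)
        coef = np.sqrt(r * s / (r + s))
        balance = coef * (logx[:, li].mean(axis=1) - logx[:, ri].mean(axis=1))
        names.append(f"n{i}")
        cols.append(balance)
    return pd.DataFrame(np.column_stack(cols), index=counts.index, columns=names)


# ---------------------------------------------------------------------------
# permutation tests


def _permanova_f(d2: np.ndarray, labels: np.ndarray, n: int, k: int) -> float:
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_among = ss_total - ss_within
    with np.errstate(divide="ignore"):
        return (ss_among / (k - 1)) / (ss_within / (n - k))


def permanova(dist: np.ndarray, groups, n_perm: int = 999, seed: int = 0
              ) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    Returns ``(pseudo_F, p)`` with ``p = (1 + #{F_perm >= F_obs}) /
    (1 + n_perm)`` under random relabeling.
    """
    d = np.asarray(dist, dtype=float)
    lab = np.unique(np.asarray(groups), return_inverse=True)[1]
    k = lab.max() + 1
    if k < 2:
        raise ValueError("need at least 2 groups")
    if np.bincount(lab).min() < 2:
        raise ValueError("every group needs at least 2 members")
    n = d.shape[0]
    d2 = d ** 2
    f_obs = _permanova_f(d2, lab, n, k)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(lab)
        if _permanova_f(d2, perm, n, k) >= f_obs:
            hits += 1
    return float(f_obs), (1 + hits) / (1 + n_perm)


def mantel(d1: np.ndarray, d2: np.ndarray, n_perm: int = 999, seed: int = 0
           ) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with permutation p.

    If DataFrames are passed their indices must match exactly.
    """
    if isinstance(d1, pd.DataFrame) and isinstance(d2, pd.DataFrame):
        if not d1.index.equals(d2.index):
            raise ValueError("distance matrices have mismatched ids")
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("distance matrices have mismatched shapes")
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    va = a[iu]
    r_obs = float(np.corrcoef(va, b[iu])[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)]
        if np.corrcoef(va, bp[iu])[0, 1] >= r_obs:
            hits += 1
    return r_obs, (1 + hits) / (1 + n_perm)


def procrustes_test(X: np.ndarray, Y: np.ndarray, n_perm: int = 999,
                    seed: int = 0) -> tuple[float, float]:
    """Procrustes m² between two ordinations with a row-permutation test."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("ordinations must share rows")
    _, _, m2 = _scipy_procrustes(X, Y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        _, _, m2p = _scipy_procrustes(X, Y[rng.permutation(Y.shape[0])])
        if m2p <= m2:
            hits += 1
    return float(m2), (1 + hits) / (1 + n_perm)


def lda_scores(coords: pd.DataFrame, labels) -> pd.DataFrame:
    """Fisher discriminant scores after a 95%-variance PCA reduction.

    PCA guards against the singular within-class scatter of high-dimensional
    balance coordinates.  Axis signs follow the convention that the first
    loading of every discriminant axis is positive.
    """
    lab = np.asarray(labels)
    classes, counts = np.unique(lab, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    X = coords.to_numpy() if isinstance(coords, pd.DataFrame) else np.asarray(coords)
    pca = PCA(n_components=0.95, svd_solver="full")
    Xr = pca.fit_transform(X)
    lda = LinearDiscriminantAnalysis(n_components=len(classes) - 1)
    scores = lda.fit_transform(Xr, lab)
    flip = np.where(lda.scalings_[0, : scores.shape[1]] < 0, -1.0, 1.0)
    scores = scores * flip
    index = coords.index if isinstance(coords, pd.DataFrame) else pd.RangeIndex(len(lab))
    return pd.DataFrame(scores, index=index,
                        columns=[f"LD{i+1}" for i in range(scores.shape[1])])


# ---------------------------------------------------------------------------
# differential ASVs


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-stable)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DifferentialFeatureSet:
    """Pairwise Wilcoxon results and the union of cluster-specific ASVs."""

    contrasts: dict[tuple[int, int], pd.DataFrame]
    cluster_specific: list[str]

    @property
    def per_contrast_counts(self) -> dict[tuple[int, int], int]:
        return {c: int(df["significant"].sum()) for c, df in self.contrasts.items()}


def differential_asvs(counts: pd.DataFrame, labels, fdr_alpha: float = 0.05,
                      log2fc_min: float = 1.0) -> DifferentialFeatureSet:
    """Cluster-specific ASVs from pairwise rank-sum tests on relative
    abundances.

    Per contrast: two-sided Wilcoxon rank-sum per ASV, BH adjustment across
    the ASVs of that contrast, log2 fold change of group-mean relative
    abundances (stabilized by a 1e-6 epsilon).  An ASV is cluster-specific
    when it passes both the FDR and the fold-change threshold in at least
    one contrast.
    """
    lab = pd.Series(np.asarray(labels), index=counts.index)
    clusters = sorted(lab.unique())
    if len(clusters) != 3:
        raise ValueError(f"expected 3 clusters, got {len(clusters)}")
    if lab.value_counts().min() < 3:
        raise ValueError("every cluster needs at least 3 samples")
    rel = relative_abundance(counts)
    out: dict[tuple[int, int], pd.DataFrame] = {}
    union: set[str] = set()
    for ai in range(len(clusters)):
        for bi in range(ai + 1, len(clusters)):
            a, b = clusters[ai], clusters[bi]
            xa = rel.loc[lab == a].to_numpy()
            xb = rel.loc[lab == b].to_numpy()
            res = stats.mannwhitneyu(xa, xb, axis=0, alternative="two-sided",
                                     method="auto")
            q = bh_adjust(res.pvalue)
            log2fc = np.log2((xa.mean(axis=0) + LOG2FC_EPS)
                             / (xb.mean(axis=0) + LOG2FC_EPS))
            sig = (q < fdr_alpha) & (np.abs(log2fc) > log2fc_min)
            df = pd.DataFrame({
                "asv_id": counts.columns,
                "p": res.pvalue,
                "q": q,
                "log2fc": log2fc,
                "direction": np.where(log2fc > 0, f"up_in_{a}", f"up_in_{b}"),
                "significant": sig,
            }).set_index("asv_id")
            out[(int(a), int(b))] = df
            union |= set(df.index[sig])
    return DifferentialFeatureSet(contrasts=out,
                                  cluster_specific=sorted(union))


def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity on relative abundances."""
    rel = relative_abundance(counts)
    d = squareform(pdist(rel.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(d, index=counts.index, columns=counts.index)
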