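"""One-vs-rest random-forest classification with leave-one-out
cross-validation and ROC/AUC.

Each sample's score is the positive-class probability from a forest trained
on all other samples; the ROC staircase and its trapezoidal area are
computed over these held-out scores.  The trapezoidal AUC equals the
Mann-Whitney U statistic normalized by n_pos * n_neg (ties counted half),
which is asserted on every run as an internal cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve

from .io import logger


def auc_trapezoid(scores, labels) -> float:
    """ROC AUC as the normalized Mann-Whitney U (ties counted half)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % 2 ** 31)


@dataclass
class ClassifierReport:
    """LOOCV result for one one-vs-rest target cluster."""

    target_cluster: int
    probabilities: pd.Series        # held-out positive-class probability
    roc_points: np.ndarray          # (fpr, tpr) rows
    auc: float
    n_trees: int
    seed: int


def rf_loocv(features: pd.DataFrame, labels, n_trees: int = 500,
             seed: int = 0, target_cluster: int = 1) -> ClassifierReport:
    """Leave-one-out random forest; per-fold seeds derive from ``seed``.

    ``labels`` is the binary one-vs-rest indicator.  Forests use sqrt(p)
    feature subsampling and bootstrap resampling per tree.
    """
    y = np.asarray(labels).astype(int)
    if y.sum() < 5 or (1 - y).sum() < 5:
        raise ValueError("need >= 5 positives and >= 5 negatives")
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    probs = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", bootstrap=True,
            random_state=_fold_seed(seed, i), n_jobs=1,
        )
        clf.fit(X[mask], y[mask])
        pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
        probs[i] = clf.predict_proba(X[i:i + 1])[0, pos_col]
        mask[i] = True

    fpr, tpr, _ = roc_curve(y, probs, drop_intermediate=False)
    auc = auc_trapezoid(probs, y)
    trap = float(np.trapezoid(tpr, fpr))
    if abs(auc - trap) > 1e-9:  # pragma: no cover - internal consistency
        raise AssertionError(f"AUC mismatch: U-based {auc} vs trapezoid {trap}")
    logger.info("cluster %d one-vs-rest LOOCV AUC %.3f", target_cluster, auc)
    return ClassifierReport(
        target_cluster=target_cluster,
        probabilities=pd.Series(probs, index=features.index, name="probability"),
        roc_points=np.column_stack([fpr, tpr]),
        auc=auc,
        n_trees=n_trees,
        seed=seed,
    )


def one_vs_rest_reports(features: pd.DataFrame, cluster_labels,
                        n_trees: int = 500, seed: int = 0
                        ) -> dict[int, ClassifierReport]:
    """One LOOCV report per cluster, positives = that cluster's samples."""
    lab = np.asarray(cluster_labels)
    out = {}
    for c in sorted(np.unique(lab)):
        out[int(c)] = rf_loocv(features, (lab == c).astype(int),
                               n_trees=n_trees, seed=seed,
                               target_cluster=int(c))
    return out
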