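"""Feature-phenotype association models and clinical group tests.

Associations follow the MaAsLin-style recipe: one ordinary least squares
model per (feature, clinical variable) pair,

    arcsin(sqrt(relative abundance)) ~ variable + age + gender,

with continuous predictors z-scored, gender as a 0/1 indicator, and
Benjamini-Hochberg adjustment across all tested pairs.  A q-value below
``assoc_q`` (default 0.25, the conventional screening threshold for these
models) flags the pair as significant.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .community import bh_adjust
from .io import ClinicalTable, logger


def associate(features: pd.DataFrame, metadata: ClinicalTable,
              variables: list[str], covariates: tuple[str, ...] = ("age", "gender"),
              assoc_q: float = 0.25) -> pd.DataFrame:
    """Per-(feature, variable) linear models on transformed abundances.

    ``features`` holds relative abundances (rows = samples matching the
    metadata participant ids).  Complete cases per pair; zero-variance
    predictors skip the pair with a logged reason.  Returns one row per
    tested pair with the variable's coefficient, p, BH q and ``significant``
    flag.
    """
    meta = metadata.data
    common = features.index.intersection(meta.index)
    if len(common) < 5:
        raise ValueError("fewer than 5 samples shared between features and metadata")
    feats = features.loc[common]
    if (feats.to_numpy() < 0).any() or (feats.to_numpy() > 1).any():
        raise ValueError("features must be relative abundances in [0, 1]")
    meta = meta.loc[common]

    cov_cols = {}
    for cov in covariates:
        if cov == "gender":
            cov_cols[cov] = (meta["gender"] == "male").astype(float).where(
                meta["gender"].notna())
        else:
            cov_cols[cov] = meta[cov].astype(float)

    rows = []
    for feature, var in itertools.product(feats.columns, variables):
        y = np.arcsin(np.sqrt(feats[feature].astype(float)))
        X = pd.DataFrame({var: meta[var].astype(float), **cov_cols})
        frame = pd.concat([y.rename("y"), X], axis=1).dropna()
        if len(frame) < len(X.columns) + 2:
            logger.warning("skipping %s ~ %s: too few complete cases",
                           feature, var)
            continue
        design = frame.drop(columns="y")
        skip = False
        for col in design.columns:
            sd = design[col].std(ddof=1)
            if sd == 0:
                logger.warning("skipping %s ~ %s: zero-variance predictor %s",
                               feature, var, col)
                skip = True
                break
            if col != "gender":
                design[col] = (design[col] - design[col].mean()) / sd
        if skip:
            continue
        model = sm.OLS(frame["y"], sm.add_constant(design)).fit()
        rows.append({
            "feature_id": feature, "variable": var,
            "coefficient": model.params[var], "p": model.pvalues[var],
            "n_used": int(model.nobs),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] < assoc_q
    return out


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p.

    All values tied across all groups gives (0, 1).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    samples = [v[g == grp] for grp in np.unique(g)]
    if len(samples) < 2 or min(len(s) for s in samples) < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    if np.ptp(v) == 0:  # all values tied across all groups
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def chi_square_counts(table) -> tuple[float, float]:
    """Pearson chi-square test of independence on an r x c count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero marginal")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def fdr_letters(pairwise_q: dict[tuple[int, int], float],
                alpha: float = 0.05) -> dict[int, str]:
    """Compact letter display from pairwise q-values.

    Clusters share a letter iff their pairwise q exceeds ``alpha``
    (not significantly different).  Letters are the maximal cliques of the
    non-significance graph, assigned A, B, ... in order of their smallest
    member.
    """
    members = sorted({c for pair in pairwise_q for c in pair})
    g = nx.Graph()
    g.add_nodes_from(members)
    for (a, b), q in pairwise_q.items():
        if q > alpha:
            g.add_edge(a, b)
    cliques = [sorted(c) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: (c[0], c))
    letters = {m: "" for m in members}
    for i, clique in enumerate(cliques):
        ch = chr(ord("A") + i)
        for m in clique:
            letters[m] += ch
    return letters
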