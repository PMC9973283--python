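"""Derived clinical quantities and preprocessing for stratification.

HOMA indices from fasting glucose (mmol/L) and insulin (μU/mL):

    HOMA-IR = G0 * I0 / 22.5
    HOMA-IS = 22.5 / (G0 * I0)
    HOMA-β  = 20 * I0 / (G0 - 3.5)      (undefined for G0 <= 3.5)

OGTT areas under the curve are trapezoidal over 0-180 min (a 0-120 min
four-point variant exists for cohorts lacking the 3-h sample).  ADA
glycemic classes use the conventional cut-offs: fasting 5.6 / 7.0 mmol/L,
2-h 7.8 / 11.1 mmol/L, HbA1c 6.5%.

Missing inputs yield missing outputs; nothing here imputes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable, OGTT_MINUTES, STRATIFICATION_VARIABLES, logger

ADA_CLASSES = ("NGT", "IFG", "IGT", "CGI", "T2D")

#: mmol/L fasting / 2-h glucose and percent HbA1c diagnostic cut-offs.
ADA_THRESHOLDS = {
    "ifg_lower": 5.6, "t2d_fasting": 7.0,
    "igt_lower": 7.8, "t2d_2h": 11.1,
    "t2d_hba1c": 6.5,
}


def homa_indices(glucose_0, insulin_0):
    """(HOMA-IR, HOMA-IS, HOMA-β) from fasting glucose and insulin.

    Accepts scalars or arrays.  Missing (NaN) inputs propagate; nonpositive
    inputs are an error.  HOMA-β is missing when glucose_0 <= 3.5 mmol/L.
    """
    g = np.asarray(glucose_0, dtype=float)
    i = np.asarray(insulin_0, dtype=float)
    if np.any(g[~np.isnan(g)] <= 0):
        raise ValueError("glucose_0 must be positive")
    if np.any(i[~np.isnan(i)] <= 0):
        raise ValueError("insulin_0 must be positive")
    prod = g * i
    homa_ir = prod / 22.5
    homa_is = 22.5 / prod
    with np.errstate(divide="ignore", invalid="ignore"):
        homa_beta = np.where(g > 3.5, 20.0 * i / (g - 3.5), np.nan)
    if np.ndim(glucose_0) == 0 and np.ndim(insulin_0) == 0:
        return float(homa_ir), float(homa_is), float(homa_beta)
    return homa_ir, homa_is, homa_beta


def ogtt_auc(values, minutes: tuple[int, ...] = OGTT_MINUTES) -> float:
    """Trapezoidal area under an OGTT time course, concentration * min.

    ``values`` must supply one concentration per requested time point;
    any missing point makes the result missing.
    """
    v = np.asarray(values, dtype=float)
    if v.shape[-1] != len(minutes):
        raise ValueError(f"expected {len(minutes)} time points, got {v.shape[-1]}")
    if np.any(v[~np.isnan(v)] < 0):
        raise ValueError("negative concentration")
    out = np.trapezoid(v, x=np.asarray(minutes, dtype=float), axis=-1)
    out = np.where(np.isnan(v).any(axis=-1), np.nan, out)
    return float(out) if out.ndim == 0 else out


def ada_classify(glucose_0, glucose_120, hba1c=np.nan) -> str | float:
    """ADA glycemic class from fasting glucose, 2-h glucose and HbA1c.

    T2D if any diagnostic threshold is met; otherwise IFG and/or IGT flags
    combine into CGI; neither flag is NGT.  Missing fasting or 2-h glucose
    makes the class missing; missing HbA1c simply cannot fire its criterion.
    """
    g0, g120 = float(glucose_0), float(glucose_120)
    a1c = float(hba1c) if hba1c is not None else np.nan
    if np.isnan(g0) or np.isnan(g120):
        return np.nan
    t = ADA_THRESHOLDS
    if g0 >= t["t2d_fasting"] or g120 >= t["t2d_2h"] or (
            not np.isnan(a1c) and a1c >= t["t2d_hba1c"]):
        return "T2D"
    ifg = t["ifg_lower"] <= g0 < t["t2d_fasting"]
    igt = t["igt_lower"] <= g120 < t["t2d_2h"]
    if ifg and igt:
        return "CGI"
    if ifg:
        return "IFG"
    if igt:
        return "IGT"
    return "NGT"


def derive_metrics(table: ClinicalTable) -> pd.DataFrame:
    """Per-participant derived metrics appended to the participant index."""
    df = table.data
    out = pd.DataFrame(index=df.index)
    ir, is_, beta = homa_indices(
        df["glucose_0"].where(df["glucose_0"] > 0),
        df["insulin_0"].where(df["insulin_0"] > 0),
    )
    out["homa_ir"], out["homa_is"], out["homa_beta"] = ir, is_, beta
    for meas in ("glucose", "insulin"):
        cols = [f"{meas}_{t}" for t in OGTT_MINUTES]
        if all(c in df for c in cols):
            out[f"{meas}_auc"] = ogtt_auc(df[cols].to_numpy())
        cols4 = cols[:4]
        if all(c in df for c in cols4):
            out[f"{meas}_auc_0_120"] = ogtt_auc(
                df[cols4].to_numpy(), minutes=OGTT_MINUTES[:4]
            )
    if "waist" in df and "hip" in df:
        out["whr"] = df["waist"] / df["hip"]
    out["ada_class"] = [
        ada_classify(g0, g120, a1c)
        for g0, g120, a1c in zip(
            df.get("glucose_0", np.nan), df.get("glucose_120", np.nan),
            df.get("hba1c", pd.Series(np.nan, index=df.index)),
        )
    ]
    return out


def cv_by_group(table: ClinicalTable, classes: pd.Series,
                variables: list[str] | None = None) -> pd.DataFrame:
    """Coefficient of variation (sample SD / mean) per variable per group.

    Missing where a group has < 2 non-missing values or a nonpositive mean.
    """
    df = table.data
    variables = variables or [
        c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])
        and c not in ("true_cluster",)
    ]
    out = {}
    for group, sub in df.groupby(classes.reindex(df.index)):
        col = {}
        for var in variables:
            vals = sub[var].dropna()
            if len(vals) < 2 or vals.mean() <= 0:
                col[var] = np.nan
            else:
                col[var] = vals.std(ddof=1) / vals.mean()
        out[group] = col
    return pd.DataFrame(out)


@dataclass
class StratificationMatrix:
    """Z-scored complete-case matrix of the stratification variables.

    ``values`` holds standardized scores for retained participants;
    ``means``/``sds`` are the scaling parameters of the retained set (needed
    to project a testing cohort onto the same scale); ``excluded`` maps each
    dropped participant to the reason ("missing" or "outlier").
    """

    values: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def excluded_ids(self) -> list[str]:
        return list(self.excluded)


def _standardize(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    means = df.mean()
    sds = df.std(ddof=1)
    zero = sds[sds == 0]
    if len(zero):
        raise ValueError(f"zero-variance columns cannot be standardized: "
                         f"{list(zero.index)}")
    return (df - means) / sds, means, sds


def build_stratification_matrix(
    table: ClinicalTable,
    variables: tuple[str, ...] = STRATIFICATION_VARIABLES,
    outlier_z: float = 5.0,
    k_max: int = 20,
    iterate: bool = False,
) -> StratificationMatrix:
    """Complete-case z-score matrix with outlier exclusion.

    Participants with any missing stratification variable are excluded
    ("missing").  Columns are z-scored on the complete-case set; rows with
    any |z| >= ``outlier_z`` are excluded ("outlier") and the retained set
    is re-standardized.  With ``iterate=True`` the exclude/re-standardize
    cycle repeats until no row violates the rule.
    """
    missing_cols = [v for v in variables if v not in table.data.columns]
    if missing_cols:
        raise ValueError(f"stratification variables absent: {missing_cols}")
    df = table.data[list(variables)].astype(float)
    excluded: dict[str, str] = {}
    complete = df.dropna()
    for pid in df.index.difference(complete.index):
        excluded[str(pid)] = "missing"
    current = complete
    while True:
        z, means, sds = _standardize(current)
        bad = z.abs().ge(outlier_z).any(axis=1)
        if not bad.any():
            break
        for pid in current.index[bad]:
            excluded[str(pid)] = "outlier"
        current = current.loc[~bad]
        if not iterate:
            z, means, sds = _standardize(current)
            break
    if len(current) < 2 * k_max:
        raise ValueError(
            f"only {len(current)} participants retained; need >= {2 * k_max}"
        )
    if excluded:
        logger.info("excluded %d participants (%s)", len(excluded),
                    ", ".join(sorted(set(excluded.values()))))
    return StratificationMatrix(values=z, means=means, sds=sds, excluded=excluded)
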