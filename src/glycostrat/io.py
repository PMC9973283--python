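"""Shared data model, readers/writers, configuration and logging.

The pipeline works on three in-memory containers:

``ClinicalTable``
    One row per participant, canonical column names (``glucose_0`` ...
    ``insulin_180``, ``hba1c``, anthropometrics, lipids).  Clinical files in
    the wild use shorthand ("FBG", "0.5-h PBG", "Ht"); a documented alias
    map translates them on read.

``AsvTable``
    A dense samples x ASVs count matrix together with a 7-rank taxonomy map
    and a rooted phylogeny whose tips cover the ASV ids.

``PipelineConfig``
    Every tunable threshold of the pipeline in one flat record, loadable
    from a YAML file, with the seed that drives all stochastic stages.

Missing values propagate as missing; nothing here imputes.  After
reconciliation, samples and ASVs are ordered lexicographically so that
outputs are reproducible across platforms.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import skbio
import yaml

logger = logging.getLogger("glycostrat")

MISSING_TOKENS = {"", "na", "n/a", "nan", "null", "none", "."}

#: The 16 clinical variables used for discovery-cohort stratification:
#: HbA1c, five OGTT glucose and five OGTT insulin time points, BMI, waist
#: and hip circumference, triglyceride and HDL.
STRATIFICATION_VARIABLES: tuple[str, ...] = (
    "hba1c",
    "glucose_0", "glucose_30", "glucose_60", "glucose_120", "glucose_180",
    "insulin_0", "insulin_30", "insulin_60", "insulin_120", "insulin_180",
    "bmi", "waist", "hip", "triglyceride", "hdl",
)

#: The 14 variables shared with a testing cohort that lacks the 3-h OGTT
#: samples (no ``glucose_180`` / ``insulin_180``).
SHARED_VARIABLES: tuple[str, ...] = tuple(
    v for v in STRATIFICATION_VARIABLES if v not in ("glucose_180", "insulin_180")
)

OGTT_MINUTES: tuple[int, ...] = (0, 30, 60, 120, 180)

_TIMEPOINT_ALIASES = {
    "0": "0", "0h": "0", "fasting": "0",
    "0.5h": "30", "0.5-h": "30", "30": "30", "30min": "30",
    "1h": "60", "1-h": "60", "60": "60", "60min": "60",
    "2h": "120", "2-h": "120", "120": "120", "120min": "120",
    "3h": "180", "3-h": "180", "180": "180", "180min": "180",
}

#: Clinical shorthand -> canonical name.  Keys are matched after
#: lower-casing and stripping spaces/parenthesised units.
VARIABLE_ALIASES: dict[str, str] = {
    "participant_id": "participant_id", "id": "participant_id",
    "sample": "participant_id", "subject": "participant_id",
    "cohort": "cohort", "age": "age", "gender": "gender", "sex": "gender",
    "hba1c": "hba1c", "bmi": "bmi",
    "ht": "height", "height": "height", "wt": "weight", "weight": "weight",
    "waist": "waist", "waist_circumference": "waist",
    "hip": "hip", "hip_circumference": "hip",
    "sbp": "sbp", "dbp": "dbp",
    "total_cholesterol": "total_cholesterol", "tc": "total_cholesterol",
    "triglyceride": "triglyceride", "tg": "triglyceride",
    "hdl": "hdl", "ldl": "ldl", "leptin": "leptin", "lbp": "lbp",
    "fbg": "glucose_0",
    "fasting_insulin": "insulin_0",
    "fasting_c_peptide": "c_peptide_0",
}
for _t in ("0", "30", "60", "120", "180"):
    VARIABLE_ALIASES[f"glucose_{_t}"] = f"glucose_{_t}"
    VARIABLE_ALIASES[f"insulin_{_t}"] = f"insulin_{_t}"
    VARIABLE_ALIASES[f"c_peptide_{_t}"] = f"c_peptide_{_t}"

_EXTRA_COLUMNS_KEPT = ("true_cluster",)


def _canonical_name(raw: str) -> str | None:
    """Map a header token to its canonical variable name, or None."""
    key = raw.strip().lower().replace(" ", "_").replace("-", "_")
    # strip a parenthesised unit such as "(mmol/L)"
    if "(" in key:
        key = key.split("(", 1)[0].rstrip("_")
    if key in VARIABLE_ALIASES:
        return VARIABLE_ALIASES[key]
    # "x.h pbg" / "x.h insulin" style time-course shorthand
    for meas, canon in (("pbg", "glucose"), ("glucose", "glucose"),
                        ("insulin", "insulin"), ("c_peptide", "c_peptide")):
        for sep in ("_",):
            if key.endswith(sep + meas):
                t = key[: -len(sep + meas)].replace("_", "")
                if t in _TIMEPOINT_ALIASES:
                    return f"{canon}_{_TIMEPOINT_ALIASES[t]}"
            if key.startswith(meas + sep):
                t = key[len(meas + sep):].replace("_", "")
                if t in _TIMEPOINT_ALIASES:
                    return f"{canon}_{_TIMEPOINT_ALIASES[t]}"
    if key in _EXTRA_COLUMNS_KEPT:
        return key
    return None


@dataclass
class ClinicalTable:
    """Participants x clinical variables, canonical names, units fixed.

    ``data`` is indexed by participant id.  ``n_warnings`` counts cells that
    could not be parsed and were recorded as missing.
    """

    data: pd.DataFrame
    n_warnings: int = 0

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise ValueError(f"duplicated participant ids: {dups}")
        for col in ("gender",):
            if col in self.data:
                bad = set(self.data[col].dropna()) - {"female", "male"}
                if bad:
                    raise ValueError(f"invalid gender values: {sorted(bad)}")
        if "cohort" in self.data:
            bad = set(self.data["cohort"].dropna()) - {"discovery", "testing"}
            if bad:
                raise ValueError(f"invalid cohort values: {sorted(bad)}")
        num = self.data.select_dtypes(include=[np.number])
        conc = [c for c in num.columns if c not in ("true_cluster",)]
        if conc and (num[conc] < 0).any().any():
            neg = [c for c in conc if (num[c] < 0).any()]
            raise ValueError(f"negative values in columns: {neg}")

    @property
    def participant_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class AsvTable:
    """Sample x ASV counts with taxonomy and a rooted phylogeny."""

    counts: pd.DataFrame                 # samples x ASVs, nonnegative ints
    taxonomy: dict[str, str]             # asv_id -> 7-rank lineage string
    tree: skbio.TreeNode                 # rooted, branch lengths present

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        tips = {t.name for t in self.tree.tips()}
        missing = set(self.counts.columns) - tips
        if missing:
            raise ValueError(f"{len(missing)} ASVs missing from the tree")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class PipelineConfig:
    """Flat record of every tunable threshold plus the master seed."""

    k_range: tuple[int, int] = (2, 20)
    outlier_z: float = 5.0
    n_bootstrap: int = 100
    n_permutations: int = 9999
    rarefaction_depth: int = 10_000
    prevalence_min: float = 0.20
    fdr_alpha: float = 0.05
    log2fc_min: float = 1.0
    assoc_q: float = 0.25
    cag_alpha: float = 0.01
    n_trees: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise ValueError("k_range lower bound must be >= 2 and <= upper")
        for name in ("prevalence_min", "fdr_alpha", "assoc_q", "cag_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.outlier_z <= 0 or self.n_permutations < 1:
            raise ValueError("outlier_z and n_permutations must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["k_range"] = list(d["k_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def configure_logging(logfile: str | Path | None = None,
                      level: int = logging.INFO) -> None:
    """Timestamped logging to stderr and optionally a file."""
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)
    logger.handlers.clear()
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(fmt)
    logger.addHandler(h)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


# ---------------------------------------------------------------------------
# readers


def read_clinical_table(path: str | Path, dialect: str = "tsv") -> ClinicalTable:
    """Read a clinical TSV/CSV into a validated :class:`ClinicalTable`.

    Header names are mapped through the alias lexicon case-insensitively;
    unrecognised columns are dropped with a log message.  Unparseable
    numeric cells become missing and are tallied in ``n_warnings``.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    raw = pd.read_csv(path, sep=sep, dtype=str)
    colmap: dict[str, str] = {}
    for col in raw.columns:
        canon = _canonical_name(col)
        if canon is None:
            logger.warning("dropping unrecognised clinical column %r", col)
        elif canon in colmap.values():
            raise ValueError(f"column {col!r} duplicates {canon!r}")
        else:
            colmap[col] = canon
    if "participant_id" not in colmap.values():
        raise ValueError("no participant_id column found")
    df = raw.rename(columns=colmap)[list(colmap.values())]
    df = df.set_index("participant_id")
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicated participant ids: {dups}")

    n_warnings = 0
    out = {}
    for col in df.columns:
        if col in ("cohort", "gender"):
            out[col] = df[col].str.strip().str.lower().where(
                ~df[col].str.strip().str.lower().isin(MISSING_TOKENS), other=pd.NA
            )
            continue
        cleaned = df[col].astype(str).str.strip()
        is_missing_token = cleaned.str.lower().isin(MISSING_TOKENS) | df[col].isna()
        parsed = pd.to_numeric(cleaned, errors="coerce")
        bad = parsed.isna() & ~is_missing_token
        if bad.any():
            n_warnings += int(bad.sum())
            logger.warning("%d unparseable cells in column %r set to missing",
                           int(bad.sum()), col)
        out[col] = parsed
    table = ClinicalTable(pd.DataFrame(out, index=df.index), n_warnings=n_warnings)
    return table


def _read_taxonomy(path: str | Path) -> dict[str, str]:
    tax = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.strip().lower(): c for c in tax.columns}
    fid = cols.get("feature id") or cols.get("feature_id") or tax.columns[0]
    txn = cols.get("taxon") or tax.columns[1]
    return dict(zip(tax[fid].astype(str), tax[txn].astype(str)))


def _read_counts(path: str | Path) -> pd.DataFrame:
    p = Path(path)
    if p.suffix == ".biom" or p.suffix == ".json":
        return _read_biom_json(p)
    return pd.read_csv(p, sep="\t", index_col=0).astype(float)


def _read_biom_json(path: Path) -> pd.DataFrame:
    """Minimal reader for (sparse or dense) JSON BIOM tables."""
    doc = json.loads(path.read_text())
    obs = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros(tuple(doc["shape"]))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[i, j] = v
    else:
        mat = np.asarray(doc["data"], dtype=float)
    # BIOM is observations x samples; pipeline orientation is samples x ASVs
    return pd.DataFrame(mat.T, index=samples, columns=obs)


def read_tree(path: str | Path) -> skbio.TreeNode:
    """Read a rooted Newick tree, insisting on branch lengths."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    if len(tree.children) > 2:
        raise ValueError("tree is unrooted (root has more than two children)")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError("tree has nodes without branch lengths")
        if node.length < 0:
            raise ValueError("tree has negative branch lengths")
    return tree


def read_asv_inputs(counts_path: str | Path, taxonomy_path: str | Path,
                    tree_path: str | Path) -> AsvTable:
    """Read and reconcile counts, taxonomy and tree into an :class:`AsvTable`.

    Count-matrix orientation is auto-detected by overlap of the axis labels
    with the taxonomy feature ids.  ASVs absent from the tree are dropped
    (count logged); remaining samples and ASVs are sorted lexicographically.
    """
    counts = _read_counts(counts_path)
    taxonomy = _read_taxonomy(taxonomy_path)
    tree = read_tree(tree_path)

    tax_ids = set(taxonomy)
    overlap_cols = len(set(counts.columns) & tax_ids)
    overlap_rows = len(set(counts.index) & tax_ids)
    if overlap_cols == 0 and overlap_rows == 0:
        raise ValueError("no ASV ids shared between counts and taxonomy")
    if overlap_rows > overlap_cols:
        counts = counts.T
    keep = sorted(set(counts.columns) & tax_ids)

    tips = {t.name for t in tree.tips()}
    in_tree = [a for a in keep if a in tips]
    n_dropped = len(keep) - len(in_tree)
    if n_dropped:
        logger.warning("dropping %d ASVs absent from the tree", n_dropped)
    counts = counts.loc[sorted(counts.index), in_tree]
    counts.index.name = "sample_id"
    counts.columns.name = None
    arr = counts.values
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts matrix contains non-integers")
    counts = counts.astype(np.int64)
    taxonomy = {a: taxonomy[a] for a in in_tree}
    return AsvTable(counts=counts, taxonomy=taxonomy, tree=tree)


# ---------------------------------------------------------------------------
# writers


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="participant_id")


def write_asv_inputs(table: AsvTable, counts_path: str | Path,
                     taxonomy_path: str | Path, tree_path: str | Path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="sample_id")
    pd.DataFrame(
        {"Feature ID": list(table.taxonomy), "Taxon": list(table.taxonomy.values())}
    ).to_csv(taxonomy_path, sep="\t", index=False)
    table.tree.write(str(tree_path), format="newick")


def write_result_bundle(results: Mapping[str, object], out_dir: str | Path,
                        manifest_extra: Mapping[str, object] | None = None) -> Path:
    """Write a dict of stage outputs as deterministic TSVs plus a manifest.

    DataFrames/Series become TSVs named after their key; scalars and dicts
    are collected into ``manifest.json`` together with ``manifest_extra``
    (parameters, seed).  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"files": [], **(manifest_extra or {})}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.tsv", sep="\t")
            manifest["files"].append(f"{name}.tsv")
        elif isinstance(obj, pd.Series):
            obj.to_frame(name).to_csv(out / f"{name}.tsv", sep="\t")
            manifest["files"].append(f"{name}.tsv")
        else:
            manifest[name] = obj
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
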