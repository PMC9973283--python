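"""Synthetic glycometabolic cohort and microbiome generator.

Emulates the statistical structure the downstream analysis assumes: a
three-cluster cohort whose clinical profiles follow published per-cluster
summary statistics (cluster 1: insulin-sensitive with the lowest glucose
and lipids; cluster 2: insulin-resistant with compensatory hypersecretion,
high BMI and lipids; cluster 3: insulin-deficient with overt hyperglycemia),
and a compositional ASV count table with a planted set of
cluster-differential taxa on a random rooted bifurcating phylogeny.

Reported dispersions are standard errors of the mean; the generator
converts them to standard deviations with ``SD = SEM * sqrt(n)`` using the
per-cluster n of each summary row.  OGTT glucose and insulin time courses
are drawn as equicorrelated multivariate normals so that a participant who
runs high at one time point tends to run high at the others.

HOMA indices and OGTT areas under the curve are never simulated — they are
derived downstream from the simulated glucose/insulin values, which keeps
derived quantities internally consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .io import AsvTable, ClinicalTable, STRATIFICATION_VARIABLES

# Per-cluster (mean, SEM, n) reference summary statistics for the discovery
# cohort.  SEMs are converted to SDs at draw time.
CLUSTER_REFERENCE_STATS: dict[str, tuple[tuple[float, float, int], ...]] = {
    "hba1c":        ((5.49, 0.03, 132), (5.76, 0.05, 96), (7.10, 0.19, 30)),
    "glucose_0":    ((5.47, 0.05, 132), (5.70, 0.08, 96), (8.45, 0.28, 30)),
    "glucose_30":   ((9.22, 0.15, 129), (10.10, 0.23, 91), (13.06, 0.50, 26)),
    "glucose_60":   ((8.77, 0.20, 129), (10.84, 0.32, 91), (16.29, 0.57, 26)),
    "glucose_120":  ((6.66, 0.14, 132), (8.76, 0.27, 96), (15.21, 0.52, 30)),
    "glucose_180":  ((4.41, 0.11, 125), (5.44, 0.21, 87), (10.12, 0.50, 26)),
    "insulin_0":    ((3.32, 0.16, 130), (6.24, 0.41, 91), (3.45, 0.53, 28)),
    "insulin_30":   ((20.88, 1.30, 127), (31.80, 2.35, 87), (6.62, 0.84, 28)),
    "insulin_60":   ((24.51, 1.29, 127), (42.33, 2.95, 87), (11.18, 1.54, 28)),
    "insulin_120":  ((19.64, 1.38, 131), (43.44, 3.77, 91), (13.15, 1.74, 28)),
    "insulin_180":  ((5.07, 0.44, 127), (14.44, 1.51, 87), (8.67, 1.19, 28)),
    "bmi":          ((23.75, 0.18, 132), (27.86, 0.28, 96), (25.17, 0.58, 30)),
    "waist":        ((80.79, 0.51, 132), (91.57, 0.67, 96), (84.82, 1.63, 30)),
    "hip":          ((92.54, 0.34, 132), (99.50, 0.57, 96), (96.04, 1.03, 30)),
    "triglyceride": ((0.66, 0.04, 127), (1.30, 0.16, 91), (1.05, 0.25, 27)),
    "hdl":          ((0.63, 0.04, 127), (0.70, 0.04, 91), (0.56, 0.08, 27)),
    "age":          ((57.42, 0.57, 131), (57.59, 0.62, 95), (60.83, 1.01, 30)),
    "height":       ((160.62, 0.67, 132), (161.81, 0.86, 96), (163.83, 1.06, 30)),
    "weight":       ((61.39, 0.68, 132), (72.88, 0.87, 96), (67.71, 1.89, 30)),
    "sbp":          ((128.62, 1.10, 132), (133.58, 1.41, 96), (127.13, 2.19, 30)),
    "dbp":          ((81.58, 0.68, 132), (83.21, 0.74, 96), (82.00, 1.55, 30)),
    "total_cholesterol": ((1.84, 0.10, 127), (2.41, 0.16, 91), (1.80, 0.25, 27)),
    "ldl":          ((1.06, 0.10, 127), (1.11, 0.10, 91), (0.80, 0.12, 27)),
}

#: Fraction of female participants per cluster (68/132, 53/96, 11/30).
FEMALE_FRACTION: tuple[float, float, float] = (68 / 132, 53 / 96, 11 / 30)

#: Lower truncation bound for simulated concentrations.
TRUNCATION_FLOOR = 0.1


def _profiles_from_reference() -> dict[str, tuple[tuple[float, float], ...]]:
    """(mean, SD) per cluster per variable, SD = SEM * sqrt(n)."""
    return {
        var: tuple((m, sem * np.sqrt(n)) for m, sem, n in rows)
        for var, rows in CLUSTER_REFERENCE_STATS.items()
    }


@dataclass
class CohortSpec:
    """Parameters of the synthetic clinical cohort."""

    n_per_cluster: tuple[int, int, int] = (132, 96, 30)
    cluster_profiles: dict[str, tuple[tuple[float, float], ...]] = field(
        default_factory=_profiles_from_reference
    )
    within_subject_corr: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_cluster):
            raise ValueError("each cluster needs at least 2 participants")
        missing = set(STRATIFICATION_VARIABLES) - set(self.cluster_profiles)
        if missing:
            raise ValueError(f"profiles missing stratification variables: {sorted(missing)}")
        for var, rows in self.cluster_profiles.items():
            for _, sd in rows:
                if sd <= 0:
                    raise ValueError(f"nonpositive SD for {var}")


@dataclass
class MicrobiomeSpec:
    """Parameters of the synthetic ASV table.

    ``n_differential`` ASVs are planted with a multiplicative abundance
    shift of ``2**planted_log2fc`` in one cluster each, assigned round-robin
    over the three pairwise contrasts.  Per-sample sequencing depths are
    log-normal with median ``depth_mean``; ``dispersion`` is the standard
    deviation of an extra per-sample log-normal noise term on abundances
    (the overdispersion knob).
    """

    n_asvs: int = 300
    n_differential: int = 67
    planted_log2fc: float = 2.0
    depth_mean: int = 20_000
    depth_sigma: float = 0.25
    dispersion: float = 0.8
    baseline_sigma: float = 1.5
    tree_seed: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_differential > self.n_asvs:
            raise ValueError("n_differential cannot exceed n_asvs")
        if self.planted_log2fc < 0:
            raise ValueError("planted_log2fc must be >= 0")


def simulate_clinical(spec: CohortSpec) -> ClinicalTable:
    """Draw a synthetic cohort; the true cluster is kept in ``true_cluster``.

    OGTT glucose and insulin series are drawn jointly (equicorrelated
    normal, correlation ``within_subject_corr``); all other variables are
    independent truncated normals from the cluster profile.  Values are
    floored at 0.1 to keep concentrations physiologic.
    """
    rng = np.random.default_rng(spec.seed)
    glucose_vars = [f"glucose_{t}" for t in (0, 30, 60, 120, 180)]
    insulin_vars = [f"insulin_{t}" for t in (0, 30, 60, 120, 180)]
    series_blocks = (glucose_vars, insulin_vars)
    block_member = {v for blk in series_blocks for v in blk}

    rows = []
    labels = []
    for c, n in enumerate(spec.n_per_cluster):
        block = {}
        for blk in series_blocks:
            mu = np.array([spec.cluster_profiles[v][c][0] for v in blk])
            sd = np.array([spec.cluster_profiles[v][c][1] for v in blk])
            p = len(blk)
            corr = np.full((p, p), spec.within_subject_corr)
            np.fill_diagonal(corr, 1.0)
            cov = corr * np.outer(sd, sd)
            draws = rng.multivariate_normal(mu, cov, size=n)
            for j, v in enumerate(blk):
                block[v] = np.maximum(draws[:, j], TRUNCATION_FLOOR)
        for var, profile in spec.cluster_profiles.items():
            if var in block_member:
                continue
            m, sd = profile[c]
            block[var] = np.maximum(rng.normal(m, sd, size=n), TRUNCATION_FLOOR)
        block["gender"] = np.where(
            rng.random(n) < FEMALE_FRACTION[c], "female", "male"
        )
        df = pd.DataFrame(block)
        df["true_cluster"] = c
        rows.append(df)
        labels.extend([c] * n)

    data = pd.concat(rows, ignore_index=True)
    total = len(data)
    data.index = pd.Index(
        [f"P{i:04d}" for i in range(total)], name="participant_id"
    )
    data.insert(0, "cohort", "discovery")
    return ClinicalTable(data=data)


@dataclass
class SyntheticMicrobiome:
    """An :class:`AsvTable` together with its planted ground truth."""

    table: AsvTable
    planted_asvs: list[str]
    #: asv_id -> cluster index in which its abundance was multiplied up
    shifted_cluster: dict[str, int]


_TAXON_LEXICON = (
    ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Prevotellaceae",
     "Prevotella", "Prevotella copri"),
    ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Bacteroidaceae",
     "Bacteroides", "Bacteroides vulgatus"),
    ("Firmicutes", "Clostridia", "Lachnospirales", "Lachnospiraceae",
     "Ruminococcus", "Ruminococcus gnavus"),
    ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Rikenellaceae",
     "Alistipes", "Alistipes shahii"),
    ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Barnesiellaceae",
     "Barnesiella", "Barnesiella intestinihominis"),
    ("Firmicutes", "Clostridia", "Oscillospirales", "Ruminococcaceae",
     "Faecalibacterium", "Faecalibacterium prausnitzii"),
    ("Firmicutes", "Clostridia", "Lachnospirales", "Lachnospiraceae",
     "Blautia", "Blautia wexlerae"),
    ("Actinobacteriota", "Actinobacteria", "Bifidobacteriales",
     "Bifidobacteriaceae", "Bifidobacterium", "Bifidobacterium longum"),
    ("Firmicutes", "Clostridia", "Lachnospirales", "Lachnospiraceae",
     "Coprococcus", "Coprococcus eutactus"),
    ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Tannerellaceae",
     "Parabacteroides", "Parabacteroides distasonis"),
)


def _lineage(i: int) -> str:
    p, c, o, f, g, s = _TAXON_LEXICON[i % len(_TAXON_LEXICON)]
    return (f"d__Bacteria; p__{p}; c__{c}; o__{o}; f__{f}; g__{g}; s__{s}")


def random_bifurcating_tree(tip_names: list[str], seed: int) -> skbio.TreeNode:
    """Rooted bifurcating tree by successive random joins.

    Branch lengths are exponential with mean 0.1, a scale typical of 16S
    ASV trees.
    """
    rng = np.random.default_rng(seed)
    nodes = [skbio.TreeNode(name=n) for n in tip_names]
    for node in nodes:
        node.length = float(rng.exponential(0.1))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = skbio.TreeNode(children=[left, right])
        parent.length = float(rng.exponential(0.1))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def simulate_asv_table(spec: MicrobiomeSpec,
                       labels: np.ndarray | pd.Series) -> SyntheticMicrobiome:
    """Compositional counts with planted cluster-differential ASVs.

    Baseline ASV abundances are log-normal; each planted ASV is multiplied
    by ``2**planted_log2fc`` in its assigned cluster; counts are multinomial
    draws at log-normal per-sample depths.
    """
    if isinstance(labels, pd.Series):
        sample_ids = [str(i) for i in labels.index]
        lab = labels.to_numpy()
    else:
        lab = np.asarray(labels)
        sample_ids = [f"P{i:04d}" for i in range(len(lab))]
    if len(lab) < 2:
        raise ValueError("need at least 2 samples")
    if len(np.unique(lab)) < 2:
        raise ValueError("labels must cover at least 2 clusters")

    rng = np.random.default_rng(spec.seed)
    n, m = len(lab), spec.n_asvs
    asv_ids = [f"ASV{i:04d}" for i in range(m)]

    baseline = np.exp(rng.normal(0.0, spec.baseline_sigma, size=m))
    diff_idx = np.sort(rng.choice(m, size=spec.n_differential, replace=False))
    # Round-robin over the three pairwise contrasts, alternating which
    # member of the contrast carries the enrichment: differential taxa end
    # up enriched in every cluster (as in real glycometabolic cohorts) and
    # the compositional load stays comparable across clusters.
    contrasts = ((0, 1), (0, 2), (1, 2))
    shifted_cluster: dict[str, int] = {}
    shift = np.ones((3, m))
    for r, idx in enumerate(diff_idx):
        up = contrasts[r % 3][(r // 3) % 2]
        shift[up, idx] = 2.0 ** spec.planted_log2fc
        shifted_cluster[asv_ids[idx]] = up

    log_noise = rng.normal(0.0, spec.dispersion, size=(n, m))
    abund = baseline[None, :] * shift[lab, :] * np.exp(log_noise)
    probs = abund / abund.sum(axis=1, keepdims=True)
    depths = np.rint(
        spec.depth_mean * np.exp(rng.normal(0.0, spec.depth_sigma, size=n))
    ).astype(np.int64)
    counts = np.empty((n, m), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(depths[i], probs[i])

    tree = random_bifurcating_tree(asv_ids, spec.tree_seed)
    taxonomy = {a: _lineage(i) for i, a in enumerate(asv_ids)}
    table = AsvTable(
        counts=pd.DataFrame(counts, index=sample_ids, columns=asv_ids),
        taxonomy=taxonomy,
        tree=tree,
    )
    return SyntheticMicrobiome(
        table=table,
        planted_asvs=[asv_ids[i] for i in diff_idx],
        shifted_cluster=shifted_cluster,
    )


def simulate_guild_counts(n_guilds: int, seed: int, guild_size: int = 6,
                          n_background: int = 100, n_samples: int = 150,
                          r_within: float = 0.9
                          ) -> tuple[pd.DataFrame, list[str]]:
    """Counts with planted co-abundance guilds on a log-normal background.

    Guild members share a common log-scale factor giving pairwise
    correlation ``r_within``; background ASVs are independent.  The guild
    size default matches what correlation-distance clustering typically
    resolves in real gut communities (a handful of ASVs per guild).
    Returns the closed integer count table and the guild member ids.
    """
    rng = np.random.default_rng(seed)
    lam = np.sqrt(r_within)
    cols: dict[str, np.ndarray] = {}
    for b in range(n_guilds):
        zb = rng.normal(size=n_samples)
        for i in range(guild_size):
            eps = rng.normal(size=n_samples)
            cols[f"B{b}_{i}"] = np.exp(lam * zb + np.sqrt(1 - lam ** 2) * eps)
    for j in range(n_background):
        cols[f"bg{j:03d}"] = np.exp(rng.normal(1.0, 1.0, size=n_samples))
    f = pd.DataFrame(cols)
    counts = (f.div(f.sum(axis=1), axis=0) * 50_000).round().astype(int)
    nodes = sorted(c for c in cols if c.startswith("B"))
    return counts, nodes


#: Default SCFA cluster means, μmol/g wet feces; concentrations fall from
#: the insulin-sensitive cluster to the insulin-deficient one.
SCFA_MEANS = {
    "butyrate": (12.0, 8.5, 5.5),
    "acetate": (60.0, 48.0, 38.0),
}
SCFA_CV = 0.35


def simulate_scfa(labels: np.ndarray | pd.Series, seed: int,
                  means: dict[str, tuple[float, float, float]] | None = None
                  ) -> pd.DataFrame:
    """Fecal butyrate/acetate with cluster means ordered c1 > c2 > c3."""
    if isinstance(labels, pd.Series):
        index = labels.index
        lab = labels.to_numpy()
    else:
        lab = np.asarray(labels)
        index = pd.RangeIndex(len(lab))
    if not np.isin(lab, [0, 1, 2]).all():
        raise ValueError("labels must be cluster indices 0..2")
    means = means or SCFA_MEANS
    rng = np.random.default_rng(seed)
    out = {}
    for scfa, mu in means.items():
        m = np.asarray(mu)[lab]
        out[scfa] = np.maximum(rng.normal(m, SCFA_CV * m), 0.0)
    return pd.DataFrame(out, index=index)
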