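# glycostrat

Unsupervised stratification of glycometabolic cohorts and discovery of
cluster-specific gut-microbiome features.

## The problem

Gut-microbiome studies of type 2 diabetes that stratify participants by
blood glucose alone report inconsistent taxa, because people in the same
glycemic range are heterogeneous in insulin sensitivity, β-cell function
and lipid metabolism. `glycostrat` implements the alternative: cluster
participants on a *joint* clinical profile — HbA1c, five-time-point OGTT
glucose and insulin, BMI, waist and hip circumference, triglyceride and
HDL (16 variables) — and only then look for microbial features that track
the resulting metabolic subtypes. It is aimed at researchers analysing
16S amplicon (ASV-level) cohort data with matched clinical tables.

## What it computes

- **Derived clinical metrics** — HOMA indices from fasting glucose `G₀`
  (mmol/L) and insulin `I₀` (μU/mL):
  `HOMA-IR = G₀·I₀/22.5`, `HOMA-IS = 22.5/(G₀·I₀)`,
  `HOMA-β = 20·I₀/(G₀ − 3.5)`; trapezoidal OGTT AUCs; ADA glycemic
  classes (NGT/IFG/IGT/CGI/T2D).
- **Stratification** — z-score the 16 variables, exclude participants with
  any |z| ≥ 5, run PAM k-medoids on Euclidean distances for k = 2…20,
  select k by maximal mean silhouette width, and assess each cluster's
  stability as its mean bootstrap Jaccard similarity (> 0.7 ≈ stable).
  Testing cohorts are projected onto the discovery cluster medians of the
  14 shared variables by nearest Euclidean center.
- **Community structure** — rarefaction; Shannon/Simpson/observed-ASV/
  Faith's PD alpha diversity; the phylogenetic isometric log-ratio (PhILR)
  transform, whose balance coordinates
  `√(rs/(r+s))·ln(g(x_L)/g(x_R))` per internal tree node make Euclidean
  distance equal the Aitchison metric; PERMANOVA, Mantel and Procrustes
  permutation tests; LDA score plots.
- **Cluster-specific ASVs** — pairwise Wilcoxon rank-sum on relative
  abundances with Benjamini–Hochberg control; an ASV is cluster-specific
  if FDR < 0.05 **and** |log₂ fold change| > 1 in at least one contrast.
- **Co-abundance networks and CAGs** — per-cluster Pearson networks over
  ASVs prevalent in > 20% of samples (edges kept at BH q < 0.05), network
  density and degree-centrality comparisons (KS tests), and co-abundance
  groups from Ward (ward.D2) clustering of correlation distance with a
  PERMANOVA-guided tree cut (p < 0.01).
- **Phenotype associations** — MaAsLin-style models
  `arcsin√(rel.abund.) ~ variable + age + gender`, BH-adjusted, screened
  at q < 0.25.
- **Classification** — one-vs-rest random forests on the cluster-specific
  ASV panel with leave-one-out cross-validation and ROC/AUC.

A synthetic-cohort generator (`simulate_clinical`, `simulate_asv_table`,
`simulate_scfa`, `simulate_guild_counts`) reproduces the statistical
structure this analysis assumes — three clinical subtypes with published
per-cluster means and dispersions, a compositional ASV table with a
planted 67-member differential set, and planted co-abundance guilds — so
the whole pipeline is testable without access to cohort data.

## Worked example

```python
import numpy as np
import glycostrat as gs

clin = gs.simulate_clinical(gs.CohortSpec(seed=1))          # 258 participants
matrix = gs.build_stratification_matrix(clin)
res = gs.select_k(matrix, (2, 20), seed=1)
print(f"selected k = {res.k}, mean silhouette = {res.silhouette:.2f}")
print(f"silhouette at k=3: {res.silhouette_by_k[3]:.2f}")
stability = gs.bootstrap_stability(matrix, 3, B=100, seed=1)
print("bootstrap Jaccard (k=3):", np.round(stability, 2))

labels = clin.data["true_cluster"].astype(int)
sim = gs.simulate_asv_table(gs.MicrobiomeSpec(seed=1, tree_seed=2), labels)
rarefied = gs.rarefy(sim.table.counts, 10_000, seed=1)
diff = gs.differential_asvs(rarefied, labels.loc[rarefied.index])
print(f"cluster-specific ASVs: {len(diff.cluster_specific)}")
```

prints

```
selected k = 2, mean silhouette = 0.34
silhouette at k=3: 0.28
bootstrap Jaccard (k=3): [0.85 0.7  0.89]
cluster-specific ASVs: 67
```

Read: on a cohort drawn at the *faithful* reference dispersions the
three metabolic subtypes overlap heavily — the silhouette profile is weak
(≈ 0.3) and the silhouette criterion may prefer k = 2; at k = 3 the
bootstrap Jaccard means still mark the clusters as borderline-stable.
Against the known subtype labels, differential calling recovers a
67-member cluster-specific ASV panel at FDR < 0.05 and |log₂FC| > 1.
`docs/methods.md` discusses why weak clinical separability is the
realistic regime and what the tests do and do not show.

A command-line interface mirrors the main stages:

```bash
glycostrat simulate --seed 5 --out cohort/
glycostrat clinical --in cohort/clinical.tsv --out cohort/derived.tsv
glycostrat stratify --clinical cohort/clinical.tsv --k-range 2 20 --seed 0 --out strat/
glycostrat run-discovery --clinical cohort/clinical.tsv --counts cohort/counts.tsv \
    --taxonomy cohort/taxonomy.tsv --tree cohort/tree.nwk --seed 0 --out results/
```

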