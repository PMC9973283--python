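# Methods

This note documents the models, numerical choices and known limitations
of `glycostrat`, in the spirit of a statistical software appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Clinical model and preprocessing

Sixteen clinical variables define the stratification space: HbA1c, OGTT
glucose and insulin at 0/30/60/120/180 min, BMI, waist and hip
circumference, triglyceride and HDL. Each column is z-scored (sample SD)
on the complete-case set; participants with any |z| ≥ 5 (config
`outlier_z`) are excluded and the retained set re-standardized. The
default is a single exclusion pass — exclusion and re-standardization are
not iterated to a fixed point — because one pass is the behavior a
practitioner gets from standard tooling and the iterated variant
(`iterate=True`) rarely changes the retained set; both are exposed.
Missing values always propagate; nothing is imputed, matching how cohort
analyses of this kind exclude rather than fill.

HOMA indices and OGTT AUCs are *always derived* from glucose/insulin,
never simulated or read from input, so the identity `HOMA-IR × HOMA-IS
= 1` and the consistency of AUC with its time course hold by
construction. HOMA-β is undefined at fasting glucose ≤ 3.5 mmol/L (pole
of the formula) and reported missing there. ADA classes use the
conventional cut-offs (fasting 5.6/7.0 mmol/L, 2-h 7.8/11.1 mmol/L,
HbA1c 6.5%); they are config-overridable constants, since diagnostic
criteria are revised over time. The 0–180 min AUC requires all five
points; a separately-named 0–120 min variant serves cohorts without the
3-h sample.

## Stratification

PAM (partitioning around medoids) is implemented directly: greedy BUILD
initialization, then steepest-descent SWAP until no single
medoid↔non-medoid exchange lowers total within-cluster distance, ties
broken toward the lowest point index. The vectorized SWAP is tested for
exact cost agreement against a brute-force swap search, and the behavior
of the overall BUILD+SWAP procedure matches the canonical R
`cluster::pam` implementation on random instances. PAM is a local
search: on small random instances it can land a few percent above the
exhaustively-enumerated optimal medoid set; this is a property of the
algorithm, not of the implementation, and the acceptance script reports
the measured match rate.

Model selection maximizes mean silhouette width over k = 2…20
(ties → smaller k); singleton clusters contribute silhouette 0. Cluster
stability follows the clusterboot recipe: B = 100 bootstrap resamples
(with replacement), PAM reclustering, and for each original cluster the
Jaccard similarity with its best-matching bootstrap cluster, restricted
to points present in the resample; means above 0.7 are flagged stable.
B = 100 balances Monte-Carlo error (≈ ±0.03 on a Jaccard mean) against
runtime. Cluster indices are renumbered by ascending mean glucose AUC so
that "cluster 1 = best glycemia" is a deterministic convention.

Testing cohorts are standardized with the *discovery* means/SDs (the
cluster centers live on the discovery z-scale) and assigned to the
nearest of the per-cluster median vectors of the 14 shared variables;
distance on the raw scale is available behind a flag for sensitivity
analyses.

## Synthetic cohort: what it emulates, and what it shows

The clinical generator draws three subtypes at published per-cluster
summary statistics, converting reported standard errors to SDs via
`SD = SEM·√n` with each row's n. OGTT glucose and insulin series are
equicorrelated multivariate normals (ρ = 0.6) so within-subject time
courses co-move; all values are floored at 0.1 to stay physiologic.
Inter-variable correlations beyond the OGTT blocks are not modeled — the
source summaries do not report them.

Two consequences deserve emphasis. First, the faithful dispersions imply
*heavily overlapping* clusters: the generated silhouette at k = 3 is
≈ 0.25, bracketing the weak silhouette (0.21) reported for the real
cohort. That realism cuts both ways: k-medoids recovers the planted
partition only partially (ARI ≈ 0.4–0.6 across seeds; the silhouette
criterion alternates between k = 2 and k = 3), so a near-perfect
parameter-recovery benchmark is not achievable in this regime, and the
package does not pretend otherwise. Unit tests of the clustering
machinery therefore use explicitly separable variants (dispersions scaled
by 0.35), while the acceptance script reports the recovery actually
measured at the faithful defaults. Second, because insulin mean shifts
between subtypes point along the high-variance direction of the
equicorrelated noise, Euclidean distance on z-scores is close to a
worst-case metric here — again mirroring the modest separability of the
real cohort.

The microbiome generator closes log-normal baseline abundances
(σ = 1.5 across ASVs), multiplies each of the 67 planted differential
ASVs by 2² in one cluster, adds per-sample log-normal noise (σ = 0.8,
the overdispersion knob), and draws multinomial counts at log-normal
depths (median 20 000, σ = 0.25). Enrichment alternates between the two
members of each pairwise contrast so that differential taxa occur in
every cluster — the structure real glycometabolic cohorts show — and so
that no single cluster carries a large one-sided compositional load.
Sequencing depth is a scaled-down stand-in (rarefaction to 10 000 reads);
all abundance-based statistics are scale-free, so behavior is identical
up to multinomial noise. Taxonomy strings come from a fixed lexicon of
gut taxa. Not emulated: batch effects, read-level error, longitudinal
sampling, taxon-taxon ecological interactions outside the planted
guilds. Passing tests therefore demonstrate the statistical machinery
under the stated generative model, not performance on raw reads.

## Community analysis

Rarefaction subsamples without replacement (multivariate hypergeometric)
to a fixed depth, dropping shallower samples. Faith's PD sums branch
lengths of the minimal subtree connecting present tips to the root,
excluding the root's own edge (stated so tests are unambiguous); the
implementation is cross-checked against scikit-bio.

The PhILR transform requires a binary tree; multifurcations are resolved
beforehand by deterministic left-branching expansion with zero-length
internal edges in tip-lexicographic order. Zeros are replaced by adding
pseudocount 1 to all counts before closure (a 0.5·minimum variant is a
parameter); balances are ordered by preorder traversal. The defining
isometry — Euclidean distance on balances equals the CLR-based Aitchison
distance — is asserted to 1e-8 against an independent CLR oracle.

PERMANOVA, Mantel and Procrustes use seeded label/row permutations with
`p = (1 + #{stat_perm ≥ stat_obs}) / (1 + n_perm)`. Note the attainable
floor of a permutation p is set by symmetry: relabelings that reproduce
the same partition tie the observed statistic, so even perfectly
separated groups of 3+3 cannot beat p = 0.1. Default permutations are
9 999 in production configs and 199–999 in tests, a pure
resolution/runtime trade-off.

Differential ASVs: two-sided Wilcoxon rank-sum per ASV per pairwise
contrast on relative abundances (scipy's exact method for small tie-free
groups, tie- and continuity-corrected normal approximation otherwise;
validated against exhaustive enumeration), BH adjustment *within* each
contrast (the per-contrast significant counts are the quantity of
interest), `log2fc = log₂((mean_A + ε)/(mean_B + ε))` with ε = 1e-6 to
guard empty features, and the cluster-specific set as the union over
contrasts of ASVs passing FDR < 0.05 and |log₂FC| > 1.

## Networks and CAGs

Per-cluster networks use ASVs present in strictly more than 20% of the
cluster's samples; Pearson correlations of relative abundances get
two-sided p-values via the t transform, BH adjustment across all tested
pairs, and edges at q < 0.05 with their sign (no additional |r|
threshold). Density is edges over possible pairs; degree centrality is
degree/(n−1); topology comparisons are two-sample KS tests on the
centrality distributions.

CAGs pool *all* samples for the correlation matrix (the node universe is
the union of the three networks' nodes, so a common correlation is
required), use the signed correlation distance d = 1 − r (preserving the
positive/negative co-abundance distinction), Ward linkage (ward.D2
convention), and a top-down tree cut: a split is kept when PERMANOVA of
the two daughter clades on the d-submatrix rejects at p < 0.01, otherwise
the clade becomes one CAG; clades under 3 members (or with a singleton
daughter, where the test is undefined) become CAGs as they stand.

A subtlety worth documenting: because Ward *chooses* each split to
maximize between-clade separation on the same distances the PERMANOVA
then tests, the split test is strongly anti-conservative for large
clades. What stops the recursion in practice is the resolution floor of
the permutation test — a clade of m ≤ 8 members admits too few distinct
two-groupings for p to fall below 0.01 (a 3|3 split has 10 distinct
groupings, so p ≥ ~0.1) — plus genuine homogeneity at small m. The
procedure therefore resolves guilds of roughly ≤ 8 ASVs, which matches
the granularity reported for real gut communities (~190 network nodes
into ~29 CAGs, ≈ 6.5 ASVs each). The planted-guild benchmarks
accordingly use guild size 6.

## Associations, group tests, classification

Associations are one OLS model per (feature, variable) pair:
`arcsin√(rel.abund.) ~ variable + age + gender`, continuous predictors
z-scored (making results scale-invariant), gender a 0/1 indicator, BH
across all pairs, screening threshold q < 0.25 (the conventional
screening level for these models; reported, not hidden). Outcome
variables are left untransformed — a documented choice where the
convention is genuinely open.

Kruskal–Wallis (tie-corrected, all-tied input defined as H = 0, p = 1),
Pearson chi-square without continuity correction, and a compact letter
display (letters = maximal cliques of the non-significance graph at
FDR 0.05, assigned in order of smallest member) cover the clinical
group comparisons.

Classification is one-vs-rest random forests (default 500 trees, √p
features per split, bootstrap per tree) under leave-one-out
cross-validation; per-fold seeds derive from `SeedSequence([seed,
fold])` so folds are independent but reproducible. AUC is computed as
the normalized Mann–Whitney U (ties half) and asserted equal to the
trapezoidal area of the ROC staircase on every run. LOOCV AUC is
pessimistically biased under the null on small n (removing a sample
unbalances its own class in training); null calibration checks use
n = 50, where the artifact is within ±0.05.

## Determinism and problem sizes

All stochastic stages draw from named substreams of a single master
seed; reruns with identical inputs and config produce byte-identical
output bundles (asserted in tests). Default test and acceptance runs use
scaled-down problem sizes chosen for a laptop-class single CPU: 258
(default) or 84 (separable) participants, 300 ASVs, rarefaction depth
10 000, 199–999 permutations, 30–200 trees; production configs restore
9 999 permutations and 500 trees.

## Known limitations

- Pearson co-abundance on relative abundances is not
  composition-aware; closure can induce spurious negative correlations
  (SparCC-type inference is out of scope by design).
- The CAG split test inherits selection bias from Ward (see above); CAG
  granularity is governed by permutation resolution as much as by
  ecology.
- The generator draws independent participants; no batch, household or
  longitudinal structure.
- k-medoids on Euclidean z-scores is the specified metric; no attempt is
  made to whiten the OGTT blocks, so correlated time points carry more
  weight than independent variables would.
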