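"""End-to-end orchestration: discovery-cohort analysis and testing-cohort
projection.

``run_discovery`` chains the stages in the order the analysis requires:
derived clinical metrics -> stratification matrix -> k-medoids model
selection and stability -> rarefaction, diversity, PhILR/PERMANOVA ->
differential ASVs -> per-cluster networks and CAGs -> feature-phenotype
associations -> one-vs-rest classifiers.  All randomness flows from the
single config seed through named substreams, so a rerun with the same
inputs and config is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import associations as assoc_mod
from . import classify, clinical, community, network, stratify
from .io import (AsvTable, ClinicalTable, PipelineConfig, SHARED_VARIABLES,
                 STRATIFICATION_VARIABLES, logger, write_result_bundle)

_STAGES = ("rarefy", "permanova", "mantel", "cags", "classify", "stability")


def _substreams(seed: int) -> dict[str, int]:
    """Named per-stage seeds derived from the master seed (all < 2^31)."""
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(len(_STAGES))
    return {name: int(s % 2 ** 31) for name, s in zip(_STAGES, states)}


@dataclass
class DiscoveryBundle:
    """Everything downstream consumers (and the testing run) need."""

    derived: pd.DataFrame
    matrix: clinical.StratificationMatrix
    result: stratify.StratificationResult
    labels: pd.Series                       # severity-ordered cluster labels
    centers: stratify.ClusterCenters
    rarefied: pd.DataFrame
    alpha: pd.DataFrame
    philr_coords: pd.DataFrame
    permanova_philr: tuple[float, float]
    differential: community.DifferentialFeatureSet
    networks: list[network.CoabundanceNetwork]
    topology: pd.DataFrame
    cags: network.CagSet
    associations: pd.DataFrame
    classifiers: dict[int, classify.ClassifierReport]
    config: PipelineConfig


def run_discovery(clinical_table: ClinicalTable, asv: AsvTable,
                  config: PipelineConfig,
                  out_dir: str | Path | None = None) -> DiscoveryBundle:
    """Full discovery-cohort analysis; optionally writes a result bundle."""
    seeds = _substreams(config.rng_seed)

    derived = clinical.derive_metrics(clinical_table)
    matrix = clinical.build_stratification_matrix(
        clinical_table, STRATIFICATION_VARIABLES,
        outlier_z=config.outlier_z, k_max=config.k_range[1],
    )
    result = stratify.select_k(matrix, config.k_range, seed=config.rng_seed)
    labels, _ = stratify.relabel_by_severity(
        result.labels, derived["glucose_auc"].reindex(result.labels.index)
    )
    result.jaccard_stability = stratify.bootstrap_stability(
        matrix, result.k, B=config.n_bootstrap, seed=seeds["stability"]
    )
    centers = stratify.compute_centers(matrix, labels)

    shared = labels.index.intersection(asv.counts.index)
    if len(shared) == 0:
        raise RuntimeError("community_analysis: no samples shared between "
                           "clinical and ASV tables")
    rarefied = community.rarefy(asv.counts.loc[shared],
                                config.rarefaction_depth, seed=seeds["rarefy"])
    lab = labels.reindex(rarefied.index)
    alpha = community.alpha_diversity(rarefied, asv.tree)
    tree = community.resolve_multifurcations(asv.tree)
    coords = community.philr_transform(rarefied, tree)
    d_philr = squareform(pdist(coords.to_numpy()))
    perma = community.permanova(d_philr, lab.to_numpy(),
                                n_perm=config.n_permutations,
                                seed=seeds["permanova"])
    differential = community.differential_asvs(
        rarefied, lab, fdr_alpha=config.fdr_alpha,
        log2fc_min=config.log2fc_min,
    )

    networks = []
    for c in sorted(lab.unique()):
        networks.append(network.build_network(
            rarefied.loc[lab == c], prevalence_min=config.prevalence_min,
            cluster_id=int(c),
        ))
    topology = network.compare_topology(networks)
    universe = sorted(set().union(*(n.nodes for n in networks)))
    cags = network.build_cags(rarefied, universe,
                              n_perm=min(config.n_permutations, 999),
                              cag_alpha=config.cag_alpha, seed=seeds["cags"])

    rel = community.relative_abundance(rarefied)
    assoc_vars = [v for v in ("hba1c", "glucose_0", "glucose_120", "bmi",
                              "triglyceride", "hdl")
                  if v in clinical_table.data.columns]
    associations = pd.DataFrame()
    if differential.cluster_specific:
        associations = assoc_mod.associate(
            rel[differential.cluster_specific], clinical_table, assoc_vars,
            assoc_q=config.assoc_q,
        )
        classifiers = classify.one_vs_rest_reports(
            rel[differential.cluster_specific], lab.to_numpy(),
            n_trees=config.n_trees, seed=seeds["classify"],
        )
    else:
        logger.warning("no cluster-specific ASVs; skipping classification")
        classifiers = {}

    bundle = DiscoveryBundle(
        derived=derived, matrix=matrix, result=result, labels=labels,
        centers=centers, rarefied=rarefied, alpha=alpha, philr_coords=coords,
        permanova_philr=perma, differential=differential, networks=networks,
        topology=topology, cags=cags, associations=associations,
        classifiers=classifiers, config=config,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: DiscoveryBundle, out_dir: str | Path) -> Path:
    results: dict[str, object] = {
        "derived_metrics": bundle.derived,
        "labels": bundle.labels.to_frame(),
        "silhouette_profile": pd.Series(bundle.result.silhouette_by_k,
                                        name="mean_silhouette"),
        "stability": pd.Series(bundle.result.jaccard_stability,
                               name="jaccard_mean"),
        "centers": bundle.centers.medians,
        "alpha_diversity": bundle.alpha,
        "philr_coords": bundle.philr_coords,
        "topology": bundle.topology,
        "associations": bundle.associations,
        "cag_membership": pd.Series(bundle.cags.membership, name="cag"),
        "selected_k": bundle.result.k,
        "silhouette": bundle.result.silhouette,
        "permanova_pseudo_f": bundle.permanova_philr[0],
        "permanova_p": bundle.permanova_philr[1],
        "auc": {c: r.auc for c, r in bundle.classifiers.items()},
    }
    for net in bundle.networks:
        results[f"edges_cluster{net.cluster_id}"] = net.edges
    extra = {"seed": bundle.config.rng_seed,
             "config": {k: str(v) for k, v in vars(bundle.config).items()}}
    return write_result_bundle(results, out_dir, manifest_extra=extra)


@dataclass
class TestingBundle:
    labels: pd.Series
    excluded: dict[str, str]
    classifiers: dict[int, classify.ClassifierReport] = field(default_factory=dict)


def run_testing(test_clinical: ClinicalTable, test_asv: AsvTable | None,
                discovery: DiscoveryBundle, config: PipelineConfig,
                retrain: bool = True) -> TestingBundle:
    """Project a testing cohort onto the discovery clusters.

    Participants are assigned to the nearest cluster center on the 14
    shared clinical variables (discovery z-scale).  If ASV counts are
    supplied, one-vs-rest classifiers are evaluated on the discovery
    feature panel — retrained on the testing cohort by LOOCV (default), or
    applied frozen from discovery.
    """
    if len(test_clinical) == 0:
        raise ValueError("empty testing cohort")
    labels, excluded = stratify.assign_to_centers(
        test_clinical, discovery.centers, outlier_z=config.outlier_z
    )
    out = TestingBundle(labels=labels, excluded=excluded)
    if test_asv is None:
        return out

    panel = discovery.differential.cluster_specific
    missing = sorted(set(panel) - set(test_asv.counts.columns))
    if missing:
        raise ValueError(f"feature panel ASVs absent from test counts: "
                         f"{missing[:10]}")
    seeds = _substreams(config.rng_seed)
    rarefied = community.rarefy(test_asv.counts, config.rarefaction_depth,
                                seed=seeds["rarefy"])
    shared = labels.index.intersection(rarefied.index)
    rel = community.relative_abundance(rarefied.loc[shared])[panel]
    lab = labels.reindex(shared).to_numpy()
    if retrain:
        out.classifiers = classify.one_vs_rest_reports(
            rel, lab, n_trees=config.n_trees, seed=seeds["classify"]
        )
    else:
        disc_rel = community.relative_abundance(discovery.rarefied)[panel]
        disc_lab = discovery.labels.reindex(disc_rel.index).to_numpy()
        from sklearn.ensemble import RandomForestClassifier
        for c in sorted(np.unique(disc_lab)):
            clf = RandomForestClassifier(
                n_estimators=config.n_trees, max_features="sqrt",
                random_state=seeds["classify"], n_jobs=1,
            )
            clf.fit(disc_rel.to_numpy(), (disc_lab == c).astype(int))
            pos = int(np.flatnonzero(clf.classes_ == 1)[0])
            probs = clf.predict_proba(rel.to_numpy())[:, pos]
            from sklearn.metrics import roc_curve
            fpr, tpr, _ = roc_curve((lab == c).astype(int), probs,
                                    drop_intermediate=False)
            out.classifiers[int(c)] = classify.ClassifierReport(
                target_cluster=int(c),
                probabilities=pd.Series(probs, index=rel.index),
                roc_points=np.column_stack([fpr, tpr]),
                auc=classify.auc_trapezoid(probs, (lab == c).astype(int)),
                n_trees=config.n_trees, seed=seeds["classify"],
            )
    return out
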