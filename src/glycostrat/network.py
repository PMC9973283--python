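"""Per-cluster co-abundance networks, topology comparison and co-abundance
groups (CAGs).

A cluster's network connects ASVs prevalent in strictly more than
``prevalence_min`` of the cluster's samples; an edge is a Pearson
correlation of relative abundances whose BH-adjusted p across all tested
pairs is below 0.05.  Density is n_edges / (n_nodes * (n_nodes - 1) / 2);
degree centrality is degree / (n_nodes - 1).

CAGs group the union of network nodes by co-abundance across ALL samples:
Ward-linkage clustering of the correlation distance d = 1 - r, then a
top-down recursion that keeps a split only when a PERMANOVA of the two
daughter clades (on the d-submatrix, clade identity as grouping) is
significant at ``cag_alpha``; otherwise the clade becomes one CAG.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .community import bh_adjust, permanova, relative_abundance
from .io import logger

MIN_CAG_TEST_SIZE = 3


def network_density(n_nodes: int, n_edges: int) -> float:
    """Fraction of realized edges among all possible node pairs."""
    if n_nodes < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return n_edges / (n_nodes * (n_nodes - 1) / 2)


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r at sample size n via the t transform."""
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return 2 * stats.t.sf(np.abs(t), df=n - 2)


@dataclass
class CoabundanceNetwork:
    """Simple undirected co-abundance graph with topology statistics."""

    cluster_id: int
    nodes: list[str]
    edges: pd.DataFrame          # asv_a, asv_b, r, p, q, sign
    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def density(self) -> float:
        return network_density(self.n_nodes, self.n_edges)

    @property
    def degree_centrality(self) -> dict[str, float]:
        return nx.degree_centrality(self.graph)


def build_network(counts: pd.DataFrame, prevalence_min: float = 0.20,
                  cluster_id: int = 0, q_max: float = 0.05
                  ) -> CoabundanceNetwork:
    """Co-abundance network of one cluster's samples.

    ``counts`` are (rarefied) counts restricted to the cluster.  Nodes are
    ASVs present in strictly more than ``prevalence_min`` of the samples;
    edges are node pairs whose Pearson correlation of relative abundances
    survives BH adjustment at ``q_max``.
    """
    n_samples = counts.shape[0]
    if n_samples < 10:
        raise ValueError(f"need >= 10 samples to build a network, got {n_samples}")
    prevalence = (counts > 0).mean(axis=0)
    nodes = sorted(counts.columns[prevalence > prevalence_min])
    if len(nodes) < 2:
        raise ValueError("fewer than 2 prevalent ASVs")
    rel = relative_abundance(counts)[nodes]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(rel.to_numpy(), rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)  # zero-variance columns: no signal
    iu = np.triu_indices(len(nodes), 1)
    r = corr[iu]
    p = _pearson_p(r, n_samples)
    q = bh_adjust(p)
    keep = q < q_max
    edges = pd.DataFrame({
        "asv_a": np.asarray(nodes)[iu[0]][keep],
        "asv_b": np.asarray(nodes)[iu[1]][keep],
        "r": r[keep],
        "p": p[keep],
        "q": q[keep],
        "sign": np.where(r[keep] > 0, "+", "-"),
    }).reset_index(drop=True)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_weighted_edges_from(edges[["asv_a", "asv_b", "r"]].itertuples(index=False))
    net = CoabundanceNetwork(cluster_id=cluster_id, nodes=nodes, edges=edges,
                             graph=g)
    logger.info("cluster %d network: %d nodes, %d edges, density %.3f",
                cluster_id, net.n_nodes, net.n_edges, net.density)
    return net


def compare_topology(networks: list[CoabundanceNetwork]) -> pd.DataFrame:
    """Pairwise two-sample KS tests on degree-centrality distributions."""
    rows = []
    for i in range(len(networks)):
        for j in range(i + 1, len(networks)):
            a, b = networks[i], networks[j]
            if a.n_nodes == 0 or b.n_nodes == 0:
                raise ValueError("empty network")
            da = list(a.degree_centrality.values())
            db = list(b.degree_centrality.values())
            ks = stats.ks_2samp(da, db, alternative="two-sided")
            rows.append({
                "network_a": a.cluster_id, "network_b": b.cluster_id,
                "ks_statistic": ks.statistic, "p": ks.pvalue,
            })
    return pd.DataFrame(rows)


@dataclass
class CagSet:
    """Partition of the node universe into co-abundance groups."""

    linkage: np.ndarray
    membership: dict[str, int]          # asv_id -> CAG index

    @property
    def n_cags(self) -> int:
        return len(set(self.membership.values()))


def build_cags(counts: pd.DataFrame, node_universe: list[str],
               n_perm: int = 999, cag_alpha: float = 0.01, seed: int = 0
               ) -> CagSet:
    """Cut a Ward tree of correlation distances into CAGs.

    Correlations pool ALL samples.  The recursion accepts a split when the
    PERMANOVA of the two daughter clades on the correlation-distance
    submatrix rejects at ``cag_alpha``; clades with fewer than 3 members
    (or an untestable singleton daughter) become CAGs as they stand.
    """
    if n_perm < 99:
        raise ValueError("n_perm < 99 cannot resolve cag_alpha")
    missing = set(node_universe) - set(counts.columns)
    if missing:
        raise ValueError(f"node universe not in counts: {sorted(missing)[:5]}")
    nodes = sorted(node_universe)
    rel = relative_abundance(counts)[nodes]
    corr = np.corrcoef(rel.to_numpy(), rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    Z = linkage(squareform(dist, checks=False), method="ward")
    root = to_tree(Z)

    membership: dict[str, int] = {}
    next_id = [0]
    rng = np.random.default_rng(seed)

    def make_cag(leaves: list[int]) -> None:
        for leaf in leaves:
            membership[nodes[leaf]] = next_id[0]
        next_id[0] += 1

    def recurse(node) -> None:
        leaves = node.pre_order(lambda x: x.id)
        if node.is_leaf() or len(leaves) < MIN_CAG_TEST_SIZE:
            make_cag(leaves)
            return
        left = node.left.pre_order(lambda x: x.id)
        right = node.right.pre_order(lambda x: x.id)
        if min(len(left), len(right)) < 2:
            make_cag(leaves)
            return
        idx = left + right
        sub = dist[np.ix_(idx, idx)]
        groups = np.array([0] * len(left) + [1] * len(right))
        _, p = permanova(sub, groups, n_perm=n_perm,
                         seed=int(rng.integers(2 ** 31)))
        if p < cag_alpha:
            recurse(node.left)
            recurse(node.right)
        else:
            make_cag(leaves)

    recurse(root)
    logger.info("%d CAGs over %d nodes", next_id[0], len(nodes))
    return CagSet(linkage=Z, membership=membership)


def summarize_cag_abundance(counts: pd.DataFrame,
                            cag_membership: dict[str, int],
                            labels) -> pd.DataFrame:
    """Z-scaled (across clusters) mean relative abundance per CAG.

    A CAG's abundance in a sample is the sum of its members' relative
    abundances; per-cluster means are z-scored across clusters within each
    CAG (sample SD).
    """
    missing = set(cag_membership) - set(counts.columns)
    if missing:
        raise ValueError(f"membership covers ASVs absent from counts: "
                         f"{sorted(missing)[:5]}")
    rel = relative_abundance(counts)
    lab = pd.Series(np.asarray(labels), index=counts.index)
    cags = sorted(set(cag_membership.values()))
    per_sample = pd.DataFrame(
        {c: rel[[a for a, m in cag_membership.items() if m == c]].sum(axis=1)
         for c in cags}
    )
    means = per_sample.groupby(lab).mean()          # clusters x CAGs
    z = (means - means.mean(axis=0)) / means.std(axis=0, ddof=1)
    z.index.name = "cluster"
    return z.T                                       # CAG x cluster
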