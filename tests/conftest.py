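"""Shared fixtures: synthetic cohorts and small hand-built tables.

``separable_cohort`` shrinks the generator's reference dispersions so that
the three clusters are cleanly recoverable — it exercises the pipeline
machinery, not the realism of the default cohort (which, like the real
study, has heavily overlapping clusters).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import glycostrat as g


def separable_spec(seed: int, n=(40, 30, 14), scale: float = 0.35) -> g.CohortSpec:
    base = g.CohortSpec(seed=seed)
    profiles = {
        var: tuple((m, sd * scale) for m, sd in rows)
        for var, rows in base.cluster_profiles.items()
    }
    return g.CohortSpec(n_per_cluster=n, cluster_profiles=profiles, seed=seed)


@pytest.fixture(scope="session")
def separable_cohort():
    """Well-separated 84-participant cohort with matched microbiome."""
    clin = g.simulate_clinical(separable_spec(3))
    truth = clin.data["true_cluster"].astype(int)
    sim = g.simulate_asv_table(g.MicrobiomeSpec(seed=3, tree_seed=4), truth)
    return clin, sim


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition cohort (faithful dispersions, 258 participants)."""
    clin = g.simulate_clinical(g.CohortSpec(seed=1))
    return clin


@pytest.fixture(scope="session")
def small_asv_sim():
    """Planted microbiome for 84 labeled samples, rarefied."""
    labels = np.repeat([0, 1, 2], [40, 30, 14])
    sim = g.simulate_asv_table(g.MicrobiomeSpec(seed=5, tree_seed=6), labels)
    rare = g.rarefy(sim.table.counts, 10_000, seed=5)
    lab = labels[[int(s[1:]) for s in rare.index]]
    return sim, rare, lab


def guild_counts(n_blocks: int, seed: int, per_block: int = 6, n_background: int = 100,
                 n_samples: int = 150, r_within: float = 0.9):
    """Planted co-abundance guilds (thin wrapper over the generator)."""
    return g.simulate_guild_counts(
        n_blocks, seed, guild_size=per_block, n_background=n_background,
        n_samples=n_samples, r_within=r_within)
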