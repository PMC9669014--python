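"""Shared fixtures: tiny hand-built genotype matrices and simulated data.

Everything is generated in memory or in tmp dirs at test time; expensive
coalescent simulations are session-scoped so several tests can share
them.
"""

from __future__ import annotations

import numpy as np
import pytest

from invapop.io_filters import MISSING, GenotypeMatrix
from invapop.synthetic_data import SimConfig, gen_structured_genotypes


def make_gm(genotypes, pops=None, chrom="chr1", pos=None, **kwargs) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a nested list (individuals x sites)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_sites = g.shape
    return GenotypeMatrix(
        genotypes=g,
        site_chrom=np.array([chrom] * n_sites, dtype=object),
        site_pos=np.arange(1, n_sites + 1) * 100 if pos is None else np.asarray(pos),
        individual_ids=[f"ind{i}" for i in range(n_ind)],
        pop_labels=None if pops is None else np.array(pops, dtype=object),
        **kwargs,
    )


@pytest.fixture(scope="session")
def panmictic_gm():
    """600 unlinked SNPs, 20 diploids, constant size 20k (one population)."""
    cfg = SimConfig(scenario="panmictic", n_individuals=20, n_snps=600,
                    n_cur=20_000, seed=7)
    gm, truth = gen_structured_genotypes(cfg)
    return gm, truth


@pytest.fixture(scope="session")
def two_deme_gm():
    """Two long-diverged demes of 8 diploids each, 150 unlinked SNPs."""
    cfg = SimConfig(scenario="two_deme_island", n_individuals=8, n_snps=150,
                    n_cur=20_000, divergence_time=30_000, seed=2)
    gm, truth = gen_structured_genotypes(cfg)
    return gm, truth


@pytest.fixture(scope="session")
def founder_expansion_gm():
    """Severe founder event (~34 diploids) growing to 5k over 1k generations."""
    cfg = SimConfig(scenario="bottleneck_C", n_individuals=20, n_snps=600,
                    n_cur=5_000, t_bot=1_000, anc_ratio=5, g_r=-0.005, seed=8)
    gm, truth = gen_structured_genotypes(cfg)
    return gm, truth
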