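"""Synthetic inputs for every pipeline stage.

Generators for RAD-like SNP genotype matrices (coalescent-simulated
with msprime under panmictic, two-deme and bottleneck scenarios), folded
site frequency spectra under the demographic models, host-plant survey
tables with planted preference weights, and paired habitat-suitability
grids with a controlled degree of overlap. Every generator is
deterministic given its seed and returns a *truth record* sufficient to
score downstream recovery experiments.

Genotype scenarios emulate the structure of RAD SNP matrices from a
recent biological invasion: tens of individuals, unlinked loci with one
SNP each strewn along one pseudo-chromosome, random missingness, and a
recent-bottleneck signal where requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import demography
from .host_use import HostSurvey
from .io_filters import MISSING, GenotypeMatrix
from .niche_overlap import SuitabilityGrid

__all__ = [
    "SimConfig",
    "gen_structured_genotypes",
    "gen_bottleneck_sfs",
    "gen_host_survey",
    "gen_suitability_pair",
]

SCENARIOS = ("panmictic", "two_deme_island", "bottleneck_B", "bottleneck_C", "full_D")


@dataclass
class SimConfig:
    """Parameters of a genotype/SFS simulation scenario.

    ``n_individuals`` is the diploid sample size *per population*;
    ``n_cur`` the present-day diploid effective size. Bottleneck
    settings follow the demographic models: ``t_bot`` generations ago
    the size jumps to ``anc_ratio * n_cur``; ``g_r`` is the
    backwards-time exponential rate of the recent epoch (model C);
    ``t_endbot``/``bot_ratio`` configure the full bottleneck (model D).
    """

    scenario: str = "panmictic"
    n_individuals: int | tuple = 20
    n_snps: int = 1000
    n_cur: float = 20_000.0
    migration_rate: float = 0.0
    divergence_time: float | None = None  # generations; None = island model
    t_bot: float = 200.0
    anc_ratio: float = 5.0
    g_r: float = 0.0
    t_endbot: float = 50.0
    bot_ratio: float = 0.01
    missing_rate: float = 0.0
    locus_spacing_bp: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.n_snps <= 0 or self.n_cur <= 0:
            raise ValueError("counts and sizes must be positive")


def _msprime_demography(cfg: SimConfig):
    """Translate a SimConfig into an msprime Demography + sample spec."""
    import msprime

    demo = msprime.Demography()
    if cfg.scenario == "two_deme_island":
        sizes = (
            cfg.n_individuals
            if isinstance(cfg.n_individuals, (tuple, list))
            else (cfg.n_individuals, cfg.n_individuals)
        )
        demo.add_population(name="pop0", initial_size=cfg.n_cur)
        demo.add_population(name="pop1", initial_size=cfg.n_cur)
        if cfg.migration_rate > 0:
            demo.set_symmetric_migration_rate(["pop0", "pop1"], cfg.migration_rate)
        if cfg.divergence_time is not None:
            demo.add_population(name="anc", initial_size=cfg.n_cur)
            demo.add_population_split(
                time=cfg.divergence_time, derived=["pop0", "pop1"], ancestral="anc"
            )
        samples = {"pop0": sizes[0], "pop1": sizes[1]}
        return demo, samples
    demo.add_population(name="pop0", initial_size=cfg.n_cur)
    if cfg.scenario == "bottleneck_B":
        demo.add_population_parameters_change(
            time=cfg.t_bot, initial_size=cfg.anc_ratio * cfg.n_cur, population="pop0"
        )
    elif cfg.scenario == "bottleneck_C":
        # backwards-time rate g_r: N(t) = n_cur * exp(g_r t); msprime's
        # growth_rate alpha gives N(t) = N0 * exp(-alpha t)
        demo = msprime_single_with_growth(cfg)
    elif cfg.scenario == "full_D":
        demo.add_population_parameters_change(
            time=cfg.t_endbot, initial_size=cfg.bot_ratio * cfg.n_cur,
            population="pop0",
        )
        demo.add_population_parameters_change(
            time=cfg.t_bot, initial_size=cfg.anc_ratio * cfg.n_cur,
            population="pop0",
        )
    n = (
        cfg.n_individuals[0]
        if isinstance(cfg.n_individuals, (tuple, list))
        else cfg.n_individuals
    )
    return demo, {"pop0": n}


def msprime_single_with_growth(cfg: SimConfig):
    import msprime

    demo = msprime.Demography()
    demo.add_population(
        name="pop0", initial_size=cfg.n_cur, growth_rate=-cfg.g_r
    )
    demo.add_population_parameters_change(
        time=cfg.t_bot, initial_size=cfg.anc_ratio * cfg.n_cur,
        growth_rate=0.0, population="pop0",
    )
    return demo


def gen_structured_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, dict]:
    """Coalescent-simulated biallelic genotypes with one SNP per locus.

    Each locus is an independent non-recombining msprime genealogy; loci
    are simulated in batches and the first biallelic SNP per locus is
    kept until ``cfg.n_snps`` sites are collected, then strewn along one
    pseudo-chromosome at ``locus_spacing_bp`` intervals. Missing
    genotypes are planted completely at random at ``missing_rate``.

    Returns the matrix plus a truth record (scenario, true K, the
    generating parameters).
    """
    import msprime

    demo, samples = _msprime_demography(cfg)
    rng = np.random.default_rng(cfg.seed)
    n_total = sum(samples.values())
    # per-locus mutation rate targeting E[segregating sites] ~ 1
    harm = np.sum(1.0 / np.arange(1, 2 * n_total))
    mu = 1.0 / (4.0 * cfg.n_cur * harm)

    cols: list[np.ndarray] = []
    batch = max(64, cfg.n_snps // 2)
    attempt = 0
    while len(cols) < cfg.n_snps and attempt < 200:
        attempt += 1
        reps = msprime.sim_ancestry(
            samples=samples,
            demography=demo,
            ploidy=2,
            sequence_length=100,
            num_replicates=batch,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        for ts in reps:
            mts = msprime.sim_mutations(
                ts,
                rate=mu / 100.0,
                random_seed=int(rng.integers(1, 2**31 - 1)),
                model=msprime.BinaryMutationModel(),
            )
            for var in mts.variants():
                g = np.asarray(var.genotypes)
                hap = (g > 0).astype(np.int8)
                if 0 < hap.sum() < hap.size:
                    cols.append(hap.reshape(-1, 2).sum(axis=1).astype(np.int8))
                    break
            if len(cols) >= cfg.n_snps:
                break
    if len(cols) < cfg.n_snps:
        raise RuntimeError("failed to collect the requested number of SNPs")

    geno = np.column_stack(cols)
    if cfg.missing_rate > 0:
        mask = rng.random(geno.shape) < cfg.missing_rate
        geno = np.where(mask, MISSING, geno).astype(np.int8)

    pops = []
    ids = []
    for pop_name, n in samples.items():
        pops.extend([pop_name] * n)
        ids.extend([f"{pop_name}_{i}" for i in range(n)])
    pos = np.arange(cfg.n_snps, dtype=np.int64) * cfg.locus_spacing_bp + 1
    gm = GenotypeMatrix(
        genotypes=geno,
        site_chrom=np.array(["chr1"] * cfg.n_snps, dtype=object),
        site_pos=pos,
        individual_ids=ids,
        pop_labels=np.array(pops, dtype=object),
    )
    truth = {
        "scenario": cfg.scenario,
        "true_K": 2 if cfg.scenario == "two_deme_island" else 1,
        "n_cur": cfg.n_cur,
        "t_bot": cfg.t_bot if cfg.scenario.startswith(("bottleneck", "full")) else None,
        "anc_ratio": cfg.anc_ratio,
        "migration_rate": cfg.migration_rate,
        "divergence_time": cfg.divergence_time,
        "seed": cfg.seed,
    }
    return gm, truth


def gen_bottleneck_sfs(cfg: SimConfig) -> tuple[demography.FoldedSFS, dict]:
    """Folded SFS simulated under a bottleneck model at a known truth.

    Uses the in-package coalescent core (one SNP per independent locus)
    so downstream model fitting is a genuine recovery experiment.
    """
    model_id = {"bottleneck_B": "B", "bottleneck_C": "C", "full_D": "D",
                "panmictic": "A"}.get(cfg.scenario)
    if model_id is None:
        raise ValueError(f"scenario {cfg.scenario!r} has no SFS model")
    params: dict = {}
    if model_id in ("B", "C", "D"):
        params["N_ANC"] = cfg.anc_ratio * cfg.n_cur
        params["T_BOT"] = cfg.t_bot
    if model_id == "C":
        params["G_R"] = cfg.g_r
    if model_id == "D":
        params["N_BOT"] = cfg.bot_ratio * cfg.n_cur
        params["T_ENDBOT"] = cfg.t_endbot
    n = (
        cfg.n_individuals[0]
        if isinstance(cfg.n_individuals, (tuple, list))
        else cfg.n_individuals
    )
    model = demography.DemographicModel(model_id=model_id, n_cur=cfg.n_cur)
    sfs = demography.simulate_sfs(model, params, n, cfg.n_snps, seed=cfg.seed)
    truth = {"model_id": model_id, "params": params, "n_individuals": n,
             "n_snps": cfg.n_snps, "n_cur": cfg.n_cur, "seed": cfg.seed}
    return sfs, truth


def gen_host_survey(
    availability: pd.DataFrame | dict,
    preference_weights: dict,
    n_attacks: int,
    seed: int = 0,
) -> tuple[HostSurvey, dict]:
    """Survey table with attacks planted at known preference weights.

    ``availability`` is either a DataFrame with columns (site, taxon,
    available) or a dict taxon -> plant count (a single site). Attacked
    plants are drawn without replacement from the plant pool with
    per-plant probability proportional to the taxon weight, so a weight
    of 1 means proportional use, > 1 preference, < 1 avoidance (the
    truth record labels each taxon accordingly).
    """
    if isinstance(availability, dict):
        avail = pd.DataFrame(
            {"site": "site1", "taxon": list(availability),
             "available": list(availability.values())}
        )
    else:
        avail = availability.copy()
    for w in preference_weights.values():
        if w <= 0:
            raise ValueError("preference weights must be positive")
    total_plants = int(avail["available"].sum())
    if n_attacks <= 0:
        raise ValueError("attack budget must be positive")
    if n_attacks > total_plants:
        raise ValueError("more attacks than available plants")
    rng = np.random.default_rng(seed)
    plant_row = np.repeat(np.arange(len(avail)), avail["available"].to_numpy())
    weights = np.array(
        [preference_weights.get(t, 1.0) for t in avail["taxon"]], dtype=float
    )
    p = weights[plant_row]
    p = p / p.sum()
    hit = rng.choice(plant_row.size, size=n_attacks, replace=False, p=p)
    attacked = np.bincount(plant_row[hit], minlength=len(avail))
    table = avail.assign(attacked=attacked)
    truth = {
        t: (
            "preference" if w > 1 else "avoidance" if w < 1 else "proportional"
        )
        for t, w in (
            (t, preference_weights.get(t, 1.0)) for t in avail["taxon"].unique()
        )
    }
    return HostSurvey(table=table), truth


def _kernel(shape: tuple, center: tuple, width: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.exp(-(((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * width**2)))


def gen_suitability_pair(
    overlap_target: str = "partial",
    shape: tuple = (40, 40),
    seed: int = 0,
    mixing: float = 0.5,
) -> tuple[SuitabilityGrid, SuitabilityGrid, dict]:
    """Two suitability grids with identical, disjoint or partial overlap.

    ``identical`` returns the same surface twice (D = I = 1);
    ``disjoint`` places the support of each grid in opposite halves
    (D = I = 0); ``partial`` mixes a shared kernel with a private one at
    the given ``mixing`` fraction (0 < D < 1).
    """
    if overlap_target not in ("identical", "disjoint", "partial"):
        raise ValueError("overlap_target must be identical|disjoint|partial")
    rng = np.random.default_rng(seed)
    h, w = shape
    jitter = lambda: rng.uniform(-2, 2)  # noqa: E731
    if overlap_target == "identical":
        base = _kernel(shape, (h / 2 + jitter(), w / 2 + jitter()), width=w / 6)
        a = b = base / base.max()
    elif overlap_target == "disjoint":
        a = _kernel(shape, (h / 2, w / 4), width=w / 12)
        b = _kernel(shape, (h / 2, 3 * w / 4), width=w / 12)
        a = np.where(np.arange(w)[None, :] < w // 2, a, 0.0)
        b = np.where(np.arange(w)[None, :] >= w // 2, b, 0.0)
        a, b = a / a.max(), b / b.max()
    else:
        shared = _kernel(shape, (h / 2, w / 2), width=w / 6)
        priv_a = _kernel(shape, (h / 4, w / 4), width=w / 10)
        priv_b = _kernel(shape, (3 * h / 4, 3 * w / 4), width=w / 10)
        a = mixing * shared + (1 - mixing) * priv_a
        b = mixing * shared + (1 - mixing) * priv_b
        a, b = a / a.max(), b / b.max()
    truth = {"overlap_target": overlap_target, "mixing": mixing, "seed": seed}
    return SuitabilityGrid(values=a), SuitabilityGrid(values=b), truth
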