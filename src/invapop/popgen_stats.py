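"""Per-population diversity statistics and pairwise differentiation.

Implements the diversity panel of a RAD-seq population survey —
expected/observed heterozygosity, multilocus F_IS with a site bootstrap,
rarefied allelic richness, private alleles, windowed Tajima's D,
per-site nucleotide diversity and the drift effective size Ne = pi/(4 mu)
— plus multilocus Weir–Cockerham theta (F_ST) with a locus bootstrap.

All estimators work on a :class:`~invapop.io_filters.GenotypeMatrix`
with missing genotypes excluded pairwise (per-site sample sizes vary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_filters import MISSING, GenotypeMatrix

__all__ = [
    "DiversitySummary",
    "FstMatrix",
    "heterozygosity",
    "fis",
    "allelic_richness",
    "private_alleles",
    "tajimas_d",
    "nucleotide_diversity",
    "effective_size",
    "pairwise_fst",
    "diversity_table",
]


@dataclass
class DiversitySummary:
    """One row of a per-population diversity table."""

    pop: object
    n: int
    he: float
    ho: float
    ar: float
    ar_sum: float
    fis: float
    fis_ci: tuple[float, float]
    tajima_d_mean: float
    tajima_d_se: float
    private_alleles: int


@dataclass
class FstMatrix:
    """Symmetric matrix of pairwise Weir–Cockerham theta estimates."""

    pops: list
    values: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pops, columns=self.pops)


# ----------------------------------------------------------------------
# heterozygosity / F_IS
# ----------------------------------------------------------------------


def _per_site_het(gm: GenotypeMatrix, pop) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (He, Ho) within one population; NaN where < 2 calls."""
    rows = gm.pop_index(pop)
    g = gm.genotypes[rows]
    called = g != MISSING
    n_ind = called.sum(axis=0).astype(float)
    alt = np.where(called, g, 0).sum(axis=0).astype(float)
    m = 2.0 * n_ind  # gene copies
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / m
        # Nei unbiased: 2p(1-p) * m/(m-1)
        he = 2.0 * p * (1.0 - p) * m / (m - 1.0)
        ho = (g == 1).sum(axis=0) / n_ind
    bad = n_ind < 2
    he[bad] = np.nan
    ho[bad] = np.nan
    return he, ho


def heterozygosity(gm: GenotypeMatrix, pop) -> tuple[float, float]:
    """Mean expected and observed heterozygosity over sites.

    He per site is the small-sample (Nei unbiased) estimate
    ``2 p (1-p) * 2n/(2n-1)`` with n the non-missing diploid count; Ho is
    the heterozygote fraction among non-missing calls. Both are averaged
    over all sites with at least two genotyped individuals.
    """
    he, ho = _per_site_het(gm, pop)
    return float(np.nanmean(he)), float(np.nanmean(ho))


def fis(
    gm: GenotypeMatrix,
    pop,
    n_boot: int = 9999,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Multilocus inbreeding coefficient with a percentile site bootstrap.

    F_IS = 1 - mean(Ho)/mean(He) (ratio of averages over sites). The CI
    resamples sites with replacement.
    """
    he, ho = _per_site_het(gm, pop)
    ok = np.isfinite(he) & np.isfinite(ho)
    he, ho = he[ok], ho[ok]
    if he.size < 2 or np.nansum(he) == 0:
        raise ValueError("F_IS undefined: no heterozygosity among usable sites")
    point = 1.0 - ho.mean() / he.mean()
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, he.size, size=(n_boot, he.size))
    he_b = he[idx].mean(axis=1)
    ho_b = ho[idx].mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        boot = 1.0 - ho_b / he_b
    boot = boot[np.isfinite(boot)]
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(point), (float(lo), float(hi))


# ----------------------------------------------------------------------
# allelic richness / private alleles
# ----------------------------------------------------------------------


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def allelic_richness(gm: GenotypeMatrix, pop, g: int) -> tuple[float, float]:
    """Rarefied allelic richness at ``g`` gene copies.

    Per site with n non-missing gene copies and n_a copies of allele a,
    Ar = sum_a [1 - C(n - n_a, g) / C(n, g)] — the expected number of
    distinct alleles in a random subsample of g copies. Returns the mean
    over sites and the sum over sites.
    """
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    rows = gm.pop_index(pop)
    alt, tot = gm.allele_counts(rows)
    usable = tot >= g
    if not usable.any():
        raise ValueError(f"no site has >= {g} gene copies in population {pop!r}")
    n = tot[usable]
    per_site = np.zeros(n.shape)
    for n_a in (alt[usable], n - alt[usable]):  # alt then ref allele
        with np.errstate(invalid="ignore"):
            log_ratio = _log_comb(n - n_a, g) - _log_comb(n, g)
        miss_prob = np.where(n - n_a >= g, np.exp(log_ratio), 0.0)
        per_site += 1.0 - miss_prob
    return float(per_site.mean()), float(per_site.sum())


def private_alleles(gm: GenotypeMatrix) -> dict:
    """Count (site, allele) pairs observed in exactly one population."""
    pops = gm.populations
    if len(pops) < 2:
        raise ValueError("private alleles require >= 2 populations")
    presence = {}  # pop -> (ref_present, alt_present) boolean arrays
    for pop in pops:
        g = gm.genotypes[gm.pop_index(pop)]
        called = g != MISSING
        ref = ((g == 0) | (g == 1)) & called
        alt = ((g == 2) | (g == 1)) & called
        presence[pop] = (ref.any(axis=0), alt.any(axis=0))
    counts = {pop: 0 for pop in pops}
    for allele_idx in (0, 1):
        mat = np.vstack([presence[pop][allele_idx] for pop in pops])
        only_one = mat.sum(axis=0) == 1
        for i, pop in enumerate(pops):
            counts[pop] += int((mat[i] & only_one).sum())
    return counts


# ----------------------------------------------------------------------
# Tajima's D / diversity
# ----------------------------------------------------------------------


def _tajima_constants(n: int) -> dict:
    """Canonical a1, a2, b1, b2, c1, c2, e1, e2 for n sequences."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(
    gm: GenotypeMatrix, pop, window_bp: int = 10_000_000
) -> tuple[pd.DataFrame, float, float]:
    """Windowed Tajima's D within one population.

    Sites are grouped into non-overlapping ``window_bp`` windows per
    chromosome. Within a window, pi is the sum of unbiased per-site
    heterozygosity over segregating sites and theta_W = S/a1; with
    missing data the constants use the median non-missing gene-copy
    count of the window's segregating sites.

    Returns (per-window table, mean D, SE of the mean across windows).
    """
    rows = gm.pop_index(pop)
    alt, tot = gm.allele_counts(rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / tot
    seg = (tot >= 4) & (p > 0) & (p < 1)
    win_key = [
        (str(c), int(pos // window_bp))
        for c, pos in zip(gm.site_chrom, gm.site_pos)
    ]
    records = []
    for key in dict.fromkeys(win_key):
        in_win = np.array([k == key for k in win_key]) & seg
        s = int(in_win.sum())
        if s == 0:
            continue
        m = tot[in_win]
        pw = p[in_win]
        pi = float(np.sum(2.0 * pw * (1.0 - pw) * m / (m - 1.0)))
        n_seq = int(np.median(m))
        if n_seq < 4:
            continue
        k = _tajima_constants(n_seq)
        var = k["e1"] * s + k["e2"] * s * (s - 1.0)
        d = (pi - s / k["a1"]) / np.sqrt(var) if var > 0 else np.nan
        records.append(
            {"chrom": key[0], "window": key[1], "n_snps": s, "pi": pi, "D": d}
        )
    if not records:
        warnings.warn("no polymorphic window for Tajima's D", stacklevel=2)
        return pd.DataFrame(columns=["chrom", "window", "n_snps", "pi", "D"]), np.nan, np.nan
    table = pd.DataFrame.from_records(records)
    d_vals = table["D"].dropna().to_numpy()
    mean = float(d_vals.mean())
    se = float(d_vals.std(ddof=1) / np.sqrt(d_vals.size)) if d_vals.size > 1 else np.nan
    return table, mean, se


def nucleotide_diversity(gm: GenotypeMatrix, pop, total_sites: int) -> float:
    """Mean pairwise difference per sequenced site (variant + invariant).

    Sums the unbiased per-site heterozygosity 2p(1-p)·m/(m-1) over
    variant sites and divides by ``total_sites``, the number of sequenced
    sites including invariant ones.
    """
    if total_sites <= 0:
        raise ValueError("total_sites must be positive")
    if total_sites < gm.n_sites:
        raise ValueError("total_sites must be >= number of variant sites")
    rows = gm.pop_index(pop)
    alt, tot = gm.allele_counts(rows)
    ok = tot >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt[ok] / tot[ok]
        per_site = 2.0 * p * (1.0 - p) * tot[ok] / (tot[ok] - 1.0)
    return float(np.nansum(per_site) / total_sites)


def effective_size(pi: float, mu: float) -> float:
    """Drift effective population size Ne = pi / (4 mu)."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    return pi / (4.0 * mu)


# ----------------------------------------------------------------------
# Weir–Cockerham theta
# ----------------------------------------------------------------------


def _wc_components(
    gm: GenotypeMatrix, pops: list
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham variance components (a, b, c).

    Two-allele, r-population form with heterozygosity correction; loci
    where no population has >= 2 genotyped individuals contribute zeros.
    """
    r = len(pops)
    n_i = np.zeros((r, gm.n_sites))
    p_i = np.zeros((r, gm.n_sites))
    h_i = np.zeros((r, gm.n_sites))
    for k, pop in enumerate(pops):
        g = gm.genotypes[gm.pop_index(pop)]
        called = g != MISSING
        n_i[k] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(called, g, 0).sum(axis=0) / (2.0 * n_i[k])
            h_i[k] = (g == 1).sum(axis=0) / n_i[k]
    usable = (n_i >= 2).all(axis=0)
    n_i, p_i, h_i = n_i[:, usable], p_i[:, usable], h_i[:, usable]
    n_tot = n_i.sum(axis=0)
    n_bar = n_tot / r
    n_c = (n_tot - (n_i**2).sum(axis=0) / n_tot) / (r - 1.0)
    p_bar = (n_i * p_i).sum(axis=0) / n_tot
    h_bar = (n_i * h_i).sum(axis=0) / n_tot
    s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1.0) * n_bar)
    pq = p_bar * (1.0 - p_bar)
    a = (n_bar / n_c) * (
        s2 - (pq - s2 * (r - 1.0) / r - h_bar / 4.0) / (n_bar - 1.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        pq - s2 * (r - 1.0) / r - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
    )
    c = h_bar / 2.0
    return a, b, c


def wc_theta(gm: GenotypeMatrix, pops: list | None = None) -> float:
    """Multilocus Weir–Cockerham theta over the given populations."""
    pops = gm.populations if pops is None else pops
    a, b, c = _wc_components(gm, pops)
    denom = (a + b + c).sum()
    if denom == 0:
        raise ValueError("Weir–Cockerham theta undefined: zero total variance")
    return float(a.sum() / denom)


def pairwise_fst(
    gm: GenotypeMatrix,
    n_boot: int = 9999,
    alpha: float = 0.05,
    seed: int = 0,
) -> FstMatrix:
    """Pairwise multilocus Weir–Cockerham theta with a locus bootstrap.

    theta = sum(a) / sum(a+b+c) over loci for each pair of populations;
    CIs are percentile bootstrap over loci (``n_boot`` replicates).
    """
    pops = gm.populations
    if len(pops) < 2:
        raise ValueError("pairwise F_ST requires >= 2 populations")
    r = len(pops)
    values = np.zeros((r, r))
    lo = np.zeros((r, r))
    hi = np.zeros((r, r))
    rng = np.random.default_rng(seed)
    for i in range(r):
        for j in range(i + 1, r):
            a, b, c = _wc_components(gm, [pops[i], pops[j]])
            denom = a + b + c
            if denom.sum() == 0:
                raise ValueError("theta undefined for pair "
                                 f"({pops[i]!r}, {pops[j]!r})")
            theta = a.sum() / denom.sum()
            n_loci = a.size
            boots = np.empty(n_boot)
            # chunked multinomial resampling over loci
            done = 0
            while done < n_boot:
                block = min(500, n_boot - done)
                w = rng.multinomial(n_loci, np.full(n_loci, 1.0 / n_loci), size=block)
                num = w @ a
                den = w @ denom
                boots[done : done + block] = np.where(den != 0, num / np.maximum(den, 1e-300), np.nan)
                done += block
            boots = boots[np.isfinite(boots)]
            qlo, qhi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            values[i, j] = values[j, i] = theta
            lo[i, j] = lo[j, i] = qlo
            hi[i, j] = hi[j, i] = qhi
    return FstMatrix(pops=pops, values=values, ci_low=lo, ci_high=hi)


# ----------------------------------------------------------------------
# summary table
# ----------------------------------------------------------------------


def diversity_table(
    gm: GenotypeMatrix,
    rarefy_to: int | None = None,
    n_boot: int = 999,
    window_bp: int = 10_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-population diversity summary (one row per population).

    ``rarefy_to`` is the rarefaction size in *diploid individuals*; the
    default uses the smallest population sample size. Columns mirror a
    standard diversity panel: N, He, Ho, Ar (per-locus mean), Fis with
    CI, mean windowed Tajima's D with SE, and private alleles.
    """
    pops = gm.populations
    priv = private_alleles(gm) if len(pops) >= 2 else {p: 0 for p in pops}
    if rarefy_to is None:
        rarefy_to = min(len(gm.pop_index(p)) for p in pops)
    rows = []
    for pop in pops:
        n = len(gm.pop_index(pop))
        he, ho = heterozygosity(gm, pop)
        try:
            ar_mean, ar_sum = allelic_richness(gm, pop, g=2 * rarefy_to)
        except ValueError:
            ar_mean, ar_sum = np.nan, np.nan
        try:
            f, ci = fis(gm, pop, n_boot=n_boot, seed=seed)
        except ValueError:
            f, ci = np.nan, (np.nan, np.nan)
        _, d_mean, d_se = tajimas_d(gm, pop, window_bp=window_bp)
        rows.append(
            DiversitySummary(
                pop=pop, n=n, he=he, ho=ho, ar=ar_mean, ar_sum=ar_sum,
                fis=f, fis_ci=ci, tajima_d_mean=d_mean, tajima_d_se=d_se,
                private_alleles=priv[pop],
            )
        )
    return pd.DataFrame(
        {
            "pop": [r.pop for r in rows],
            "N": [r.n for r in rows],
            "He": [r.he for r in rows],
            "Ho": [r.ho for r in rows],
            "Ar": [r.ar for r in rows],
            "Ar_sum": [r.ar_sum for r in rows],
            "Fis": [r.fis for r in rows],
            "Fis_lo": [r.fis_ci[0] for r in rows],
            "Fis_hi": [r.fis_ci[1] for r in rows],
            "TajimaD": [r.tajima_d_mean for r in rows],
            "TajimaD_SE": [r.tajima_d_se for r in rows],
            "PA": [r.private_alleles for r in rows],
        }
    )
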