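"""VCF input/output and SNP-matrix filtering.

The entry point of the pipeline: read diploid biallelic genotype calls
from a VCF, apply the site-level filters used for RAD-style SNP matrices
(allele count, per-site missingness, mean read depth, monomorphy, minor
allele frequency, an external exclusion list), drop high-missingness
individuals, and prune sites in strong linkage disequilibrium with a
PLINK-style sliding window.

Genotypes are stored as the count of the alternate allele (0, 1, 2) with
``MISSING`` (= -1) marking uncalled genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

MISSING: int = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "FilterSpec",
    "VcfParseError",
    "UnsupportedPloidyError",
    "read_vcf",
    "write_vcf",
    "filter_sites",
    "filter_individuals",
    "ld_prune",
    "vif_to_r2",
]


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed."""


class UnsupportedPloidyError(ValueError):
    """Raised when genotype calls are not diploid."""


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for a set of individuals at SNP sites.

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_sites)`` integer array; entries are the count
        of the alternate allele (0, 1 or 2) or ``MISSING``.
    site_chrom
        Chromosome/scaffold identifier per site.
    site_pos
        1-based coordinate per site; strictly increasing within a chrom.
    individual_ids
        One label per row of ``genotypes``.
    pop_labels
        Population assignment per individual (optional).
    site_depth
        Mean read depth per site (optional, coverage units).
    site_n_alleles
        Number of alleles observed in the source VCF record (optional;
        sites with more than two are flagged for the max-alleles filter).
    """

    genotypes: np.ndarray
    site_chrom: np.ndarray
    site_pos: np.ndarray
    individual_ids: list
    pop_labels: np.ndarray | None = None
    site_depth: np.ndarray | None = None
    site_n_alleles: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.site_chrom = np.asarray(self.site_chrom, dtype=object)
        self.site_pos = np.asarray(self.site_pos, dtype=np.int64)
        self.individual_ids = list(self.individual_ids)
        if self.pop_labels is not None:
            self.pop_labels = np.asarray(self.pop_labels, dtype=object)
            if len(self.pop_labels) != self.n_individuals:
                raise ValueError("pop_labels length must equal n_individuals")
        if self.site_depth is not None:
            self.site_depth = np.asarray(self.site_depth, dtype=float)
        if self.site_n_alleles is not None:
            self.site_n_alleles = np.asarray(self.site_n_alleles, dtype=np.int64)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x sites)")
        if len(self.site_chrom) != self.n_sites or len(self.site_pos) != self.n_sites:
            raise ValueError("site annotation length mismatch")
        if len(self.individual_ids) != self.n_individuals:
            raise ValueError("individual_ids length mismatch")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype values must be in {0,1,2,MISSING}")
        for chrom in np.unique(self.site_chrom.astype(str)):
            pos = self.site_pos[self.site_chrom.astype(str) == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"site_pos not strictly increasing on {chrom}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def populations(self) -> list:
        if self.pop_labels is None:
            return []
        seen: list = []
        for p in self.pop_labels:
            if p not in seen:
                seen.append(p)
        return seen

    # -- subsetting -----------------------------------------------------
    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, index],
            site_chrom=self.site_chrom[index],
            site_pos=self.site_pos[index],
            individual_ids=self.individual_ids,
            pop_labels=self.pop_labels,
            site_depth=None if self.site_depth is None else self.site_depth[index],
            site_n_alleles=None
            if self.site_n_alleles is None
            else self.site_n_alleles[index],
        )

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            genotypes=self.genotypes[index, :],
            site_chrom=self.site_chrom,
            site_pos=self.site_pos,
            individual_ids=[self.individual_ids[i] for i in index],
            pop_labels=None if self.pop_labels is None else self.pop_labels[index],
            site_depth=self.site_depth,
            site_n_alleles=self.site_n_alleles,
        )

    def pop_index(self, pop) -> np.ndarray:
        """Row indices of the individuals assigned to ``pop``."""
        if self.pop_labels is None:
            raise ValueError("GenotypeMatrix has no population labels")
        idx = np.flatnonzero(self.pop_labels == pop)
        if idx.size == 0:
            raise KeyError(f"unknown population: {pop!r}")
        return idx

    # -- per-site summaries ---------------------------------------------
    def allele_counts(self, rows: np.ndarray | None = None):
        """Alternate-allele copies and non-missing gene copies per site.

        Returns ``(alt_copies, total_copies)`` arrays of length n_sites,
        computed over ``rows`` (default: all individuals), skipping
        missing genotypes.
        """
        g = self.genotypes if rows is None else self.genotypes[rows]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0).astype(float)
        tot = 2.0 * called.sum(axis=0)
        return alt, tot

    def site_missing_fraction(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)

    def individual_missing_fraction(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=1)


# ----------------------------------------------------------------------
# filters
# ----------------------------------------------------------------------


def vif_to_r2(vif: float) -> float:
    """Pairwise-r² equivalent of a variance-inflation-factor threshold.

    VIF = 1/(1-R²), so a VIF cutoff of 2 corresponds to r² = 0.5.
    """
    if vif <= 1:
        raise ValueError("VIF threshold must exceed 1")
    return 1.0 - 1.0 / vif


@dataclass
class FilterSpec:
    """Thresholds for the site/individual filtering cascade.

    Defaults mirror a RAD-seq SNP cleaning recipe: biallelic sites only,
    site missingness <= 25%, mean site depth within 6-100X, individuals
    with > 45% missing data dropped, MAF >= 0.03 (set ``maf_min=None``
    to keep rare variants, as required for demographic inference), and
    PLINK-style LD pruning with window 50 sites / step 5 / VIF 2.
    """

    max_alleles: int = 2
    max_site_missing: float = 0.25
    depth_min: float | None = 6.0
    depth_max: float | None = 100.0
    max_indiv_missing: float = 0.45
    maf_min: float | None = 0.03
    ld_window: int = 50
    ld_step: int = 5
    ld_vif: float = 2.0
    exclude_sites: Sequence[tuple] | None = None  # (chrom, pos) pairs

    def __post_init__(self) -> None:
        for frac in (self.max_site_missing, self.max_indiv_missing):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("missingness thresholds must be in [0, 1]")
        if self.maf_min is not None and not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5] or None")
        if (
            self.depth_min is not None
            and self.depth_max is not None
            and self.depth_min > self.depth_max
        ):
            raise ValueError("depth_min must not exceed depth_max")
        if self.ld_step > self.ld_window:
            raise ValueError("ld_step must not exceed ld_window")

    @classmethod
    def from_file(cls, path) -> "FilterSpec":
        """Load thresholds from a YAML/key-value config file."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ValueError("filter config must be a mapping of key: value")
        return cls(**raw)


#: order in which site filters are applied and counted
FILTER_ORDER = ("alleles", "missingness", "depth", "monomorphic", "maf", "excluded")


def filter_sites(
    gm: GenotypeMatrix, spec: FilterSpec | None = None
) -> tuple[GenotypeMatrix, dict]:
    """Apply the site-level filtering cascade.

    Filters run in the fixed order ``alleles -> missingness -> depth ->
    monomorphic -> MAF -> exclusion list``; each removal is attributed to
    the first criterion that rejects the site, so the per-criterion
    counts sum to the total number of sites removed.

    Returns the filtered matrix and a dict of removal counts keyed by
    criterion name.
    """
    if spec is None:
        spec = FilterSpec()
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")

    keep = np.ones(gm.n_sites, dtype=bool)
    removed: dict = {k: 0 for k in FILTER_ORDER}

    def drop(mask: np.ndarray, name: str) -> None:
        mask = mask & keep
        removed[name] = int(mask.sum())
        keep[mask] = False

    # 1. allele count
    if gm.site_n_alleles is not None:
        drop(gm.site_n_alleles > spec.max_alleles, "alleles")
    # 2. per-site missingness
    drop(gm.site_missing_fraction() > spec.max_site_missing, "missingness")
    # 3. mean depth window
    if gm.site_depth is not None and (
        spec.depth_min is not None or spec.depth_max is not None
    ):
        bad = np.zeros(gm.n_sites, dtype=bool)
        if spec.depth_min is not None:
            bad |= gm.site_depth < spec.depth_min
        if spec.depth_max is not None:
            bad |= gm.site_depth > spec.depth_max
        drop(bad, "depth")
    # 4. monomorphic among non-missing calls
    alt, tot = gm.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    drop((tot == 0) | (p <= 0.0) | (p >= 1.0), "monomorphic")
    # 5. minor allele frequency
    if spec.maf_min is not None:
        maf = np.minimum(p, 1.0 - p)
        drop(maf < spec.maf_min, "maf")
    # 6. external exclusion list (e.g. outlier SNPs)
    if spec.exclude_sites:
        excl = {(str(c), int(pp)) for c, pp in spec.exclude_sites}
        listed = np.array(
            [
                (str(c), int(pp)) in excl
                for c, pp in zip(gm.site_chrom, gm.site_pos)
            ]
        )
        drop(listed, "excluded")

    if not keep.any():
        warnings.warn("all sites removed by filtering", stacklevel=2)
    return gm.take_sites(np.flatnonzero(keep)), removed


def filter_individuals(
    gm: GenotypeMatrix, max_missing: float = 0.45
) -> GenotypeMatrix:
    """Drop individuals whose missing-genotype fraction exceeds ``max_missing``."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    keep = np.flatnonzero(gm.individual_missing_fraction() <= max_missing)
    return gm.take_individuals(keep)


def _pairwise_r2(g: np.ndarray, i: int, j: int) -> float:
    """Squared genotype correlation between two sites, pairwise-complete."""
    a, b = g[:, i], g[:, j]
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_prune(
    gm: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_threshold: float | None = None,
    vif: float = 2.0,
) -> GenotypeMatrix:
    """PLINK-style sliding-window LD pruning on genotype correlations.

    Within each window of ``window`` consecutive sites (advanced by
    ``step``, never crossing a chromosome boundary) the later site of any
    retained pair with r² above the threshold is dropped. The threshold
    defaults to the pairwise-r² equivalent of the VIF cutoff
    (``1 - 1/vif``). Deterministic given the input site order.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    thr = vif_to_r2(vif) if r2_threshold is None else r2_threshold
    keep = np.ones(gm.n_sites, dtype=bool)
    g = gm.genotypes
    chroms = gm.site_chrom.astype(str)
    for chrom in dict.fromkeys(chroms):  # preserves order
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx):
            win = idx[start : start + window]
            for a_pos in range(len(win)):
                i = win[a_pos]
                if not keep[i]:
                    continue
                for b_pos in range(a_pos + 1, len(win)):
                    j = win[b_pos]
                    if not keep[j]:
                        continue
                    if _pairwise_r2(g, i, j) > thr:
                        keep[j] = False
            if start + window >= len(idx):
                break
            start += step
    return gm.take_sites(np.flatnonzero(keep))


# ----------------------------------------------------------------------
# VCF I/O
# ----------------------------------------------------------------------


def read_vcf(path, pop_map: Mapping[str, object] | None = None) -> GenotypeMatrix:
    """Read diploid GT calls (and per-site mean depth) from a VCF.

    Multi-allelic records are retained with ``site_n_alleles`` recording
    the allele count so the max-alleles filter can drop them; their
    genotype encoding counts copies of the first ALT allele. Missing
    calls map to ``MISSING``.

    ``pop_map`` optionally assigns a population label per sample id.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib raises bare OSError/Exception
        raise VcfParseError(f"cannot parse VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"VCF {path!r} contains no samples")

    cols: list[np.ndarray] = []
    chroms: list[str] = []
    poss: list[int] = []
    nall: list[int] = []
    depth: list[float] = []
    any_depth = False
    for line_no, var in enumerate(vcf, start=1):
        geno = var.genotypes  # [[a0, a1, phased], ...]
        col = np.empty(len(samples), dtype=np.int8)
        for i, call in enumerate(geno):
            alleles = call[:-1]
            if len(alleles) != 2:
                raise UnsupportedPloidyError(
                    f"non-diploid genotype for sample {samples[i]} at "
                    f"{var.CHROM}:{var.POS} (record {line_no})"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                col[i] = MISSING
            else:
                col[i] = int(alleles[0] == 1) + int(alleles[1] == 1)
        cols.append(col)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        nall.append(1 + len(var.ALT))
        d = _site_mean_depth(var, len(samples))
        if d is not None:
            any_depth = True
        depth.append(np.nan if d is None else d)
    if not cols:
        raise VcfParseError(f"VCF {path!r} contains no variant records")

    return GenotypeMatrix(
        genotypes=np.column_stack(cols),
        site_chrom=np.array(chroms, dtype=object),
        site_pos=np.array(poss, dtype=np.int64),
        individual_ids=samples,
        pop_labels=None
        if pop_map is None
        else np.array([pop_map.get(s) for s in samples], dtype=object),
        site_depth=np.array(depth) if any_depth else None,
        site_n_alleles=np.array(nall, dtype=np.int64),
    )


def _site_mean_depth(var, n_samples: int) -> float | None:
    try:
        fmt_dp = var.format("DP")
    except Exception:
        fmt_dp = None
    if fmt_dp is not None:
        vals = np.asarray(fmt_dp, dtype=float).ravel()
        vals = vals[np.isfinite(vals) & (vals >= 0)]
        if vals.size:
            return float(vals.mean())
    dpm = var.INFO.get("DPM")
    if dpm is not None:
        return float(dpm)
    info_dp = var.INFO.get("DP")
    if info_dp is not None:
        return float(info_dp) / n_samples
    return None


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT calls (and site mean depth as INFO DPM)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DPM,Number=1,Type=Float,Description="Mean site depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(gm.site_chrom.astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, gm.individual_ids))
            + "\n"
        )
        for j in range(gm.n_sites):
            info = "."
            if gm.site_depth is not None and np.isfinite(gm.site_depth[j]):
                info = f"DPM={gm.site_depth[j]:.3f}"
            gts = "\t".join(_GT_STRINGS[int(g)] for g in gm.genotypes[:, j])
            fh.write(
                f"{gm.site_chrom[j]}\t{gm.site_pos[j]}\t.\tA\tT\t.\tPASS\t"
                f"{info}\tGT\t{gts}\n"
            )
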