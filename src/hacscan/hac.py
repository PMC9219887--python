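"""Haplotype allelic classes (HAC) and the normalized variance difference (nvd).

The HAC of a haplotype over a window of SNPs is the number of minor
alleles it carries across the window (focal SNP excluded).  A selective
sweep drags one allele at the focal SNP to high frequency together with
the haplotype background it arose on, so the haplotypes carrying the
favoured (major) allele become unusually similar: the variance of their
HACs collapses relative to the haplotypes carrying the other allele.

nvd contrasts the HAC variances of the two focal-allele partitions,
normalized by their sum so values are scale-free across window sizes and
bounded in [-1, 1]:

    nvd = (var_minor - var_major) / (var_major + var_minor)

Positive nvd — a homogeneous major-allele partition — is the sweep
signature, and nvd -> 1 as the major partition collapses to identical
haplotypes.  (Normalizing by the population's total HAC variance instead
penalizes exactly the swept focal SNP, where the separation between the
two partitions inflates the total variance.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import HaplotypeMatrix, PopulationPair

__all__ = ["Window", "PartitionStats", "NvdResult", "build_window",
           "hac_values", "partition_stats", "nvd"]

MIN_WINDOW_MEMBERS = 3


@dataclass(frozen=True)
class Window:
    """A focal SNP and its flanking SNPs among the shared SNP set.

    ``member_indices`` are the columns (into the PopulationPair) of the at
    most ``size_snps`` SNPs centred on ``focal_index``, all on the focal
    SNP's chromosome; windows truncate at chromosome ends rather than
    shift.
    """

    focal_index: int
    size_snps: int
    member_indices: np.ndarray

    def __post_init__(self) -> None:
        members = np.asarray(self.member_indices, dtype=np.intp)
        object.__setattr__(self, "member_indices", members)
        if self.focal_index not in members:
            raise ValueError("focal_index must be a window member")
        if members.size < MIN_WINDOW_MEMBERS:
            raise ValueError(
                f"window has {members.size} members; at least "
                f"{MIN_WINDOW_MEMBERS} required"
            )

    @property
    def flank_indices(self) -> np.ndarray:
        return self.member_indices[self.member_indices != self.focal_index]


def build_window(snps, focal_index: int, size_snps: int) -> Window:
    """Build the window of ``size_snps`` SNPs centred on ``focal_index``.

    ceil((L-1)/2) SNPs are taken upstream and floor((L-1)/2) downstream
    (relevant for even L); membership is restricted to the focal SNP's
    chromosome and truncated at its ends.
    """
    if size_snps < MIN_WINDOW_MEMBERS:
        raise ValueError(f"size_snps must be >= {MIN_WINDOW_MEMBERS}")
    n = len(snps)
    if not 0 <= focal_index < n:
        raise IndexError(f"focal_index {focal_index} out of range for {n} SNPs")
    chroms = snps["chrom"].to_numpy()
    focal_chrom = chroms[focal_index]
    up = -((size_snps - 1) // -2)  # ceil
    down = (size_snps - 1) // 2
    lo = focal_index - up
    hi = focal_index + down
    idx = np.arange(max(lo, 0), min(hi, n - 1) + 1)
    idx = idx[chroms[idx] == focal_chrom]
    return Window(focal_index=focal_index, size_snps=size_snps, member_indices=idx)


def _minor_allele_codes(freqs: np.ndarray) -> np.ndarray:
    """Allele code (0/1) of the minor allele per SNP; ties go to allele 1.

    With frequency of allele 1 exactly 0.5 either choice gives identical
    HAC *variances* (complementary counts); allele 1 is used for
    determinism.
    """
    return np.where(freqs > 0.5, 0, 1).astype(np.int8)


def pooled_minor_alleles(pair: PopulationPair) -> np.ndarray:
    """Minor-allele code per shared SNP, from the pooled two-population sample."""
    return _minor_allele_codes(pair.pooled_frequencies())


def hac_values(
    matrix: HaplotypeMatrix,
    window: Window,
    minor_alleles: np.ndarray | None = None,
) -> np.ndarray:
    """HAC per haplotype: minor-allele count over the window, focal excluded.

    ``minor_alleles`` gives the minor allele code per SNP column of the
    matrix; pass :func:`pooled_minor_alleles` of the pair so HACs are
    comparable between populations (the default derives it from this
    matrix alone).
    """
    if window.member_indices.size < MIN_WINDOW_MEMBERS:
        raise ValueError("window too small")
    if window.member_indices.max() >= matrix.n_snps:
        raise IndexError("window indices out of range for matrix")
    if minor_alleles is None:
        minor_alleles = _minor_allele_codes(matrix.allele_frequencies())
    flank = window.flank_indices
    h = matrix.haplotypes[:, flank]
    return (h == minor_alleles[flank]).sum(axis=1).astype(np.int64)


@dataclass
class PartitionStats:
    """HAC variance statistics of the two focal-allele partitions.

    "major" is the more frequent focal allele *within this population*
    (ties broken toward allele coded 0).  Variances are sample variances
    (denominator n-1); a partition with fewer than two haplotypes has
    undefined variance, stored as NaN.  The raw HAC vectors are kept for
    the robust variance tests downstream.
    """

    population_label: str
    major_allele: int
    n_major: int
    n_minor: int
    var_major: float
    var_minor: float
    var_total: float
    hac_major: np.ndarray
    hac_minor: np.ndarray

    def __post_init__(self) -> None:
        if self.n_major < self.n_minor:
            raise ValueError("n_major must be >= n_minor")


def _sample_var(x: np.ndarray) -> float:
    return float(np.var(x, ddof=1)) if x.size >= 2 else float("nan")


def partition_stats(
    matrix: HaplotypeMatrix,
    window: Window,
    minor_alleles: np.ndarray | None = None,
) -> PartitionStats:
    """Partition haplotypes by focal allele and compute HAC variances."""
    focal = matrix.haplotypes[:, window.focal_index]
    n1 = int(focal.sum())
    n0 = focal.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError(
            f"focal SNP (column {window.focal_index}) is monomorphic in "
            f"population {matrix.population_label!r}"
        )
    major_allele = 1 if n1 > n0 else 0  # tie -> allele 0
    hac = hac_values(matrix, window, minor_alleles)
    in_major = focal == major_allele
    hac_major = hac[in_major]
    hac_minor = hac[~in_major]
    return PartitionStats(
        population_label=matrix.population_label,
        major_allele=major_allele,
        n_major=int(hac_major.size),
        n_minor=int(hac_minor.size),
        var_major=_sample_var(hac_major),
        var_minor=_sample_var(hac_minor),
        var_total=_sample_var(hac),
        hac_major=hac_major,
        hac_minor=hac_minor,
    )


@dataclass
class NvdResult:
    """Per-population nvd at one focal SNP and their pair summary (max)."""

    snp_id: str
    size_snps: int
    nvd_pop1: float
    nvd_pop2: float

    @property
    def pair_nvd(self) -> float:
        return max(self.nvd_pop1, self.nvd_pop2)


def _nvd_from_stats(stats: PartitionStats) -> float:
    denom = stats.var_major + stats.var_minor
    if not np.isfinite(denom) or denom == 0:
        return 0.0
    return (stats.var_minor - stats.var_major) / denom


def nvd(
    pair: PopulationPair,
    window: Window,
    minor_alleles: np.ndarray | None = None,
) -> NvdResult:
    """Normalized variance difference at the window's focal SNP.

    Per population: (var_minor - var_major) / (var_major + var_minor),
    defined as 0 when both partition variances vanish or either
    partition has fewer than two haplotypes (no contrast to measure).
    HAC minor alleles are defined on the pooled pair;
    precompute them with :func:`pooled_minor_alleles` when calling in a
    loop.
    """
    minors = pooled_minor_alleles(pair) if minor_alleles is None else minor_alleles
    s1 = partition_stats(pair.pop1, window, minors)
    s2 = partition_stats(pair.pop2, window, minors)
    return NvdResult(
        snp_id=str(pair.snps["snp_id"].iloc[window.focal_index]),
        size_snps=window.size_snps,
        nvd_pop1=_nvd_from_stats(s1),
        nvd_pop2=_nvd_from_stats(s2),
    )
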