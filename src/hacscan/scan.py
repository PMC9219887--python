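"""Genome-scan mode (nvd + FST) and the multi-method consensus combiner.

The scan ranks every shared SNP by its pair nvd at each window size and
takes the top fraction (default 1%) per size as provisional outliers; a
SNP becomes a candidate when it is a top-nvd SNP for at least one window
size *and* its focal-SNP FST rejects panmixia.  The FST permutation test
does not depend on window size, so it is run once per provisional SNP.

The consensus combiner is plain list algebra over the significant-SNP
sets of independent scan methods (e.g., an LD-decay scan, this scan, and
a multilocus-FST-variance scan): keep SNPs called by at least ``k``
methods, with a per-method membership table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .fst import all_site_fst, fst_panmixia_test
from .hac import MIN_WINDOW_MEMBERS, build_window, nvd, pooled_minor_alleles
from .io import PopulationPair

__all__ = [
    "ScanConfig",
    "ScanResult",
    "MethodCallSet",
    "nvd_fst_scan",
    "consensus",
    "cross_comparison_overlap",
]


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the genome scan."""

    window_sizes: tuple[int, ...] = (1000, 500, 250, 125, 62)
    top_fraction: float = 0.01
    alpha: float = 0.05
    n_permutations: int = 999
    seed: int | None = None
    estimator: str = "hudson"

    def __post_init__(self) -> None:
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must lie in (0, 1]")
        if any(s < MIN_WINDOW_MEMBERS for s in self.window_sizes):
            raise ValueError("window sizes must be >= 3")
        if not self.window_sizes:
            raise ValueError("at least one window size required")


@dataclass
class ScanResult:
    """Per-SNP scan table plus the final candidate set."""

    table: pd.DataFrame
    candidates: set[str]
    config: ScanConfig

    def candidate_bed(self) -> pd.DataFrame:
        """BED-like frame (chrom, pos-1, pos, snp_id) of the candidates."""
        sub = self.table[self.table["snp_id"].isin(self.candidates)]
        return pd.DataFrame(
            {
                "chrom": sub["chrom"],
                "start": sub["pos_bp"] - 1,
                "end": sub["pos_bp"],
                "snp_id": sub["snp_id"],
            }
        ).reset_index(drop=True)


def _top_mask(values: np.ndarray, top_fraction: float) -> np.ndarray:
    """Boolean mask of the top `top_fraction` values, ties included.

    The cutoff is the value at rank ceil(top_fraction * n); every SNP at
    or above the cutoff is kept, so ties at the boundary all enter.
    NaNs never qualify.
    """
    finite = np.isfinite(values)
    n = int(finite.sum())
    if n == 0:
        return np.zeros_like(values, dtype=bool)
    k = max(1, ceil(top_fraction * n))
    cutoff = np.sort(values[finite])[::-1][k - 1]
    return finite & (values >= cutoff)


def nvd_fst_scan(pair: PopulationPair, config: ScanConfig = ScanConfig()) -> ScanResult:
    """Scan all shared SNPs: pair nvd per window size + FST gate.

    Requires at least 1/top_fraction shared SNPs (otherwise "top 1%" is
    meaningless).  SNPs whose window has fewer than 3 members (sparse
    chromosome ends) get NaN nvd for that size.  Output is sorted by
    (chrom, pos_bp); ties in nvd at the ranking boundary are all kept.
    """
    n = pair.n_snps
    if n < int(round(1.0 / config.top_fraction)):
        raise ValueError(
            f"scan needs at least {int(round(1.0 / config.top_fraction))} shared "
            f"SNPs for top_fraction={config.top_fraction}; got {n}"
        )
    # windows are SNP-adjacency based: enforce genomic column order up front
    # so the scan is invariant to how the input columns were arranged
    genomic = np.lexsort(
        (pair.snps["pos_bp"].to_numpy(), pair.snps["chrom"].to_numpy())
    )
    if not np.array_equal(genomic, np.arange(n)):
        pair = PopulationPair(
            pop1=pair.pop1.take_snps(genomic), pop2=pair.pop2.take_snps(genomic)
        )
    snps = pair.snps
    minors = pooled_minor_alleles(pair)
    cols: dict[int, np.ndarray] = {}
    for L in config.window_sizes:
        vals = np.full(n, np.nan)
        for j in range(n):
            try:
                window = build_window(snps, j, L)
            except ValueError:
                continue
            vals[j] = nvd(pair, window, minors).pair_nvd
        cols[L] = vals

    top_any = np.zeros(n, dtype=bool)
    top_by_size: dict[int, np.ndarray] = {}
    for L, vals in cols.items():
        mask = _top_mask(vals, config.top_fraction)
        top_by_size[L] = mask
        top_any |= mask

    ss = np.random.SeedSequence(config.seed if config.seed is not None else None)
    rng = np.random.default_rng(ss)
    fst = all_site_fst(pair, config.estimator)
    fst_p = np.full(n, np.nan)
    for j in np.flatnonzero(top_any):
        fst_p[j] = fst_panmixia_test(
            pair, j, n_permutations=config.n_permutations, seed=rng,
            estimator=config.estimator,
        ).p_value

    candidate = top_any & (fst_p <= config.alpha)
    table = pd.DataFrame(
        {
            "snp_id": snps["snp_id"],
            "chrom": snps["chrom"],
            "pos_bp": snps["pos_bp"],
            **{f"nvd_L{L}": cols[L] for L in config.window_sizes},
            **{f"top_L{L}": top_by_size[L] for L in config.window_sizes},
            "fst": fst,
            "fst_p": fst_p,
            "candidate": candidate,
        }
    )
    order = np.lexsort((table["pos_bp"].to_numpy(), table["chrom"].to_numpy()))
    table = table.iloc[order].reset_index(drop=True)
    return ScanResult(
        table=table,
        candidates=set(table.loc[table["candidate"], "snp_id"]),
        config=config,
    )


@dataclass
class MethodCallSet:
    """The significant-SNP list of one detection method."""

    method_name: str
    snp_ids: set[str] = field(default_factory=set)

    @classmethod
    def from_tsv(cls, path, method_name: str | None = None) -> "MethodCallSet":
        """Read a one-column (or `snp_id`-columned) TSV of significant SNPs."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        col = "snp_id" if "snp_id" in df.columns else df.columns[0]
        ids = set(df[col].dropna())
        name = method_name or str(path)
        return cls(method_name=name, snp_ids=ids)


def consensus(
    call_sets: list[MethodCallSet], k: int = 2
) -> tuple[set[str], pd.DataFrame]:
    """SNPs called by at least ``k`` methods, plus the membership table.

    The table has one row per SNP appearing in any set, one boolean
    column per method, the number of supporting methods, and a
    combination label joining the supporting method names (the
    "X-N / X-S / N-S / X-N-S" cell structure of multi-method summaries).
    """
    if not call_sets:
        raise ValueError("no call sets given")
    if k < 1:
        raise ValueError("k must be >= 1")
    names = [cs.method_name for cs in call_sets]
    if len(set(names)) != len(names):
        raise ValueError("method names must be unique")
    all_ids = sorted(set().union(*(cs.snp_ids for cs in call_sets)))
    table = pd.DataFrame({"snp_id": all_ids})
    for cs in call_sets:
        table[cs.method_name] = table["snp_id"].isin(cs.snp_ids)
    table["n_methods"] = table[names].sum(axis=1)
    table["combination"] = table[names].apply(
        lambda row: "-".join(n for n in names if row[n]), axis=1
    )
    selected = set(table.loc[table["n_methods"] >= k, "snp_id"])
    return selected, table


def cross_comparison_overlap(
    calls_a: MethodCallSet, calls_b: MethodCallSet
) -> tuple[set[str], pd.DataFrame]:
    """SNPs shared between two comparisons' call sets, with provenance."""
    shared = calls_a.snp_ids & calls_b.snp_ids
    table = pd.DataFrame(
        {
            "snp_id": sorted(shared),
            "source_a": calls_a.method_name,
            "source_b": calls_b.method_name,
        }
    )
    return shared, table
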