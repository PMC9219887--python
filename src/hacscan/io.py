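"""Reading phased genotypes, SNP-array quality control, and population pairing.

Input formats
-------------
* Phased VCF (uncompressed or bgzipped) with diploid ``GT`` fields, read via
  :mod:`cyvcf2`.  Genotypes must be phased (``0|1``); unphased or missing
  calls raise, because every downstream statistic operates on haplotypes.
* Plain haplotype table (TSV): one row per haplotype, one column per SNP,
  entries in {0, 1} (-1 marks a missing call, only meaningful before QC).
* Population map (TSV): columns ``sample_id``, ``population``.
* SNP map (TSV): columns ``snp_id``, ``chrom``, ``pos_bp``, ``allele_a``,
  ``allele_b``.

The central container is :class:`HaplotypeMatrix` — a binary haplotype ×
SNP matrix for one population plus an ordered SNP metadata table.  Two
populations restricted to their mutually polymorphic SNPs form a
:class:`PopulationPair`, the unit every statistic consumes.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SNPMeta",
    "HaplotypeMatrix",
    "QCConfig",
    "QCReport",
    "PopulationPair",
    "read_phased_vcf",
    "read_haplotype_table",
    "write_haplotype_table",
    "apply_qc",
    "make_pair",
]

MISSING = -1

#: Chromosome labels treated as "not mapped" by the QC unmapped filter.
UNMAPPED_CHROMS = frozenset({"", "0", "NA", "na", "none", "None", "."})

SNP_COLUMNS = ["snp_id", "chrom", "pos_bp", "allele_a", "allele_b"]


@dataclass(frozen=True)
class SNPMeta:
    """Metadata for one biallelic SNP (1-based physical position)."""

    snp_id: str
    chrom: str
    pos_bp: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"SNP {self.snp_id}: alleles must differ")


def _snp_frame(snps) -> pd.DataFrame:
    """Normalise SNP metadata (DataFrame or iterable of SNPMeta) to a frame."""
    if isinstance(snps, pd.DataFrame):
        df = snps.reset_index(drop=True).copy()
    else:
        df = pd.DataFrame([vars(s) for s in snps])
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNP table missing columns: {missing}")
    df["pos_bp"] = df["pos_bp"].astype(np.int64)
    df["chrom"] = df["chrom"].astype(str)
    return df[SNP_COLUMNS]


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes of one population.

    Rows are haplotypes (two consecutive rows per diploid individual, in
    sample order), columns are SNPs ordered by (chrom, pos_bp).  Entries
    are 0 (allele_a) or 1 (allele_b); -1 marks missing calls and is only
    tolerated before QC.
    """

    population_label: str
    haplotypes: np.ndarray
    snps: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        self.snps = _snp_frame(self.snps)
        if self.haplotypes.shape[1] != len(self.snps):
            raise ValueError(
                f"{self.haplotypes.shape[1]} haplotype columns but "
                f"{len(self.snps)} SNP records"
            )
        if self.haplotypes.shape[0] % 2:
            raise ValueError("odd haplotype count: expected 2 per diploid sample")
        bad = ~np.isin(self.haplotypes, (0, 1, MISSING))
        if bad.any():
            raise ValueError("haplotype entries must be 0, 1 or -1 (missing)")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def has_missing(self) -> bool:
        return bool((self.haplotypes == MISSING).any())

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of allele 1 per SNP, over non-missing calls."""
        h = self.haplotypes
        obs = h != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(obs, h, 0).sum(axis=0) / obs.sum(axis=0)

    def take_snps(self, idx: np.ndarray) -> "HaplotypeMatrix":
        """Subset columns, preserving order of ``idx``."""
        return HaplotypeMatrix(
            population_label=self.population_label,
            haplotypes=self.haplotypes[:, idx],
            snps=self.snps.iloc[np.asarray(idx)].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the SNP-array QC filter chain.

    Defaults follow standard array practice for this kind of data:
    per-SNP call rate > 0.97, pooled minor allele frequency >= 0.01, and
    removal of SNPs without a mapped chromosome position.
    """

    min_call_rate: float = 0.97
    min_maf: float = 0.01
    drop_unmapped: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must lie in [0, 1]")
        if not 0.0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must lie in [0, 0.5)")


@dataclass
class QCReport:
    """Per-filter SNP removal counts, in application order."""

    n_input: int
    removed: dict[str, int]
    n_remaining: int

    def to_frame(self) -> pd.DataFrame:
        rows = [(name, n) for name, n in self.removed.items()]
        df = pd.DataFrame(rows, columns=["filter", "n_removed"])
        df["n_remaining"] = self.n_input - df["n_removed"].cumsum()
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class PopulationPair:
    """Two populations restricted to identically ordered shared SNPs.

    Every retained SNP is polymorphic within each population, the
    precondition of the focal-SNP partition statistics.
    """

    pop1: HaplotypeMatrix
    pop2: HaplotypeMatrix

    def __post_init__(self) -> None:
        if not self.pop1.snps["snp_id"].equals(self.pop2.snps["snp_id"]):
            raise ValueError("pair populations must share an identical SNP list")

    @property
    def snps(self) -> pd.DataFrame:
        return self.pop1.snps

    @property
    def n_snps(self) -> int:
        return self.pop1.n_snps

    def snp_index(self, snp_id: str) -> int:
        """Column index of ``snp_id``; raises with nearest neighbours if absent."""
        ids = self.snps["snp_id"]
        hits = np.flatnonzero(ids.to_numpy() == snp_id)
        if hits.size:
            return int(hits[0])
        raise KeyError(
            f"SNP {snp_id!r} is not in the shared SNP set of the pair "
            f"({self.n_snps} SNPs); it may have been removed by QC or be "
            "monomorphic in one population. "
            + _nearest_hint(self.snps, snp_id)
        )

    def pooled_frequencies(self) -> np.ndarray:
        """Allele-1 frequency per SNP over both populations pooled."""
        h = np.vstack([self.pop1.haplotypes, self.pop2.haplotypes])
        return h.mean(axis=0)


def _nearest_hint(snps: pd.DataFrame, snp_id: str) -> str:
    # Useful when a candidate was QC'd out: point at retained neighbours.
    prefix = snp_id.rsplit("_", 1)[0]
    near = snps[snps["snp_id"].str.startswith(prefix)]
    if len(near):
        names = ", ".join(near["snp_id"].head(5))
        return f"Nearest shared SNPs by name: {names}."
    return "No similarly named shared SNPs found."


# ---------------------------------------------------------------------------
# readers / writers


def read_popmap(path) -> pd.DataFrame:
    pm = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "population"} <= set(pm.columns):
        # headerless two-column form
        pm = pd.read_csv(path, sep="\t", header=None, dtype=str,
                         names=["sample_id", "population"])
    return pm[["sample_id", "population"]]


def read_phased_vcf(path, popmap_path, *, on_multiallelic: str = "error"):
    """Read a phased diploid VCF into one :class:`HaplotypeMatrix` per population.

    Parameters
    ----------
    path : str
        VCF with phased ``GT`` for every sample listed in the popmap.
    popmap_path : str
        TSV mapping ``sample_id`` to ``population``.
    on_multiallelic : {"error", "skip"}
        Whether a site with more than two alleles aborts or is skipped
        with a warning.

    Returns
    -------
    list of HaplotypeMatrix, ordered by population label.  Haplotype rows
    follow popmap sample order, two per sample (transmitted order as
    phased in the VCF); allele_b (the VCF ALT) is coded 1.
    """
    from cyvcf2 import VCF

    if on_multiallelic not in ("error", "skip"):
        raise ValueError("on_multiallelic must be 'error' or 'skip'")
    popmap = read_popmap(popmap_path)
    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    missing_samples = set(vcf_samples) - set(popmap["sample_id"])
    if missing_samples:
        raise ValueError(
            f"samples in VCF but absent from popmap: {sorted(missing_samples)}"
        )
    sample_pos = {s: i for i, s in enumerate(vcf_samples)}
    absent = [s for s in popmap["sample_id"] if s not in sample_pos]
    if absent:
        raise ValueError(f"popmap samples not present in VCF: {absent}")

    rows_meta: list[SNPMeta] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            if on_multiallelic == "skip":
                import warnings

                warnings.warn(
                    f"skipping multiallelic site {var.CHROM}:{var.POS}",
                    stacklevel=2,
                )
                continue
            raise ValueError(f"multiallelic site at {var.CHROM}:{var.POS}")
        gts = var.genotypes  # [a, b, phased] per sample
        col = np.empty(2 * len(vcf_samples), dtype=np.int8)
        for i, (a, b, *rest) in enumerate(gts):
            phased = bool(rest[-1]) if rest else False
            if a < 0 or b < 0:
                raise ValueError(
                    f"missing genotype for sample {vcf_samples[i]} at "
                    f"{var.CHROM}:{var.POS}; phased complete input required"
                )
            if not phased:
                raise ValueError(
                    f"unphased genotype for sample {vcf_samples[i]} at "
                    f"{var.CHROM}:{var.POS}"
                )
            col[2 * i] = a
            col[2 * i + 1] = b
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        rows_meta.append(
            SNPMeta(snp_id, str(var.CHROM), int(var.POS), var.REF, var.ALT[0])
        )
        columns.append(col)
    if not columns:
        raise ValueError("VCF contains no usable biallelic sites")
    full = np.column_stack(columns)
    snps = _snp_frame(rows_meta)

    out = []
    for pop, grp in popmap.groupby("population", sort=True):
        hap_rows = []
        samples = list(grp["sample_id"])
        for s in samples:
            j = sample_pos[s]
            hap_rows.extend([2 * j, 2 * j + 1])
        out.append(
            HaplotypeMatrix(
                population_label=str(pop),
                haplotypes=full[hap_rows, :],
                snps=snps,
                sample_ids=samples,
            )
        )
    return out


def write_phased_vcf(matrices: list[HaplotypeMatrix], path) -> None:
    """Write populations as a phased diploid VCF (uncompressed text).

    All matrices must share a SNP list; consecutive haplotype rows are
    paired into diploid samples.  Sample names fall back to
    ``<population>_s<i>`` when the matrix carries no sample ids.
    """
    if not matrices:
        raise ValueError("no matrices given")
    snps = matrices[0].snps
    for m in matrices[1:]:
        if not m.snps["snp_id"].equals(snps["snp_id"]):
            raise ValueError("matrices must share a SNP list")
        if m.has_missing():
            raise ValueError("cannot write missing calls to a phased VCF")
    names: list[str] = []
    for m in matrices:
        if m.sample_ids:
            names.extend(m.sample_ids)
        else:
            names.extend(
                f"{m.population_label}_s{i}" for i in range(m.n_haplotypes // 2)
            )
    h = np.vstack([m.haplotypes for m in matrices])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in snps["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        for j, snp in snps.iterrows():
            gts = "\t".join(
                f"{h[2 * i, j]}|{h[2 * i + 1, j]}" for i in range(len(names))
            )
            fh.write(
                f"{snp.chrom}\t{snp.pos_bp}\t{snp.snp_id}\t{snp.allele_a}\t"
                f"{snp.allele_b}\t.\t.\t.\tGT\t{gts}\n"
            )


def write_popmap(matrices: list[HaplotypeMatrix], path) -> None:
    """Write the sample→population TSV matching :func:`write_phased_vcf`."""
    rows = []
    for m in matrices:
        samples = m.sample_ids or [
            f"{m.population_label}_s{i}" for i in range(m.n_haplotypes // 2)
        ]
        rows.extend((s, m.population_label) for s in samples)
    pd.DataFrame(rows, columns=["sample_id", "population"]).to_csv(
        path, sep="\t", index=False
    )


def write_haplotype_table(matrix: HaplotypeMatrix, path) -> None:
    """Write a TSV with one row per haplotype, header = snp_id."""
    df = pd.DataFrame(matrix.haplotypes, columns=matrix.snps["snp_id"])
    df.insert(0, "haplotype", [f"{matrix.population_label}_h{i}"
                               for i in range(matrix.n_haplotypes)])
    df.to_csv(path, sep="\t", index=False)


def read_haplotype_table(path, snp_map, population_label: str) -> HaplotypeMatrix:
    """Read a haplotype TSV back; ``snp_map`` is a SNP metadata TSV or frame."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] == "haplotype":
        df = df.drop(columns="haplotype")
    if isinstance(snp_map, (str, bytes, _io.IOBase)) or hasattr(snp_map, "__fspath__"):
        snp_map = pd.read_csv(snp_map, sep="\t", dtype={"chrom": str})
    snps = _snp_frame(snp_map).set_index("snp_id").loc[list(df.columns)].reset_index()
    return HaplotypeMatrix(
        population_label=population_label,
        haplotypes=df.to_numpy(dtype=np.int8),
        snps=snps,
    )


# ---------------------------------------------------------------------------
# QC and pairing


def apply_qc(
    matrices: list[HaplotypeMatrix], qc: QCConfig = QCConfig()
) -> tuple[list[HaplotypeMatrix], QCReport]:
    """Apply the SNP QC chain: unmapped -> low call rate -> low pooled MAF.

    All matrices must share a SNP list; filters act on SNP columns only so
    haplotype counts are conserved.  MAF is computed on the sample pooled
    across populations.  Raises if no SNP survives.
    """
    if not matrices:
        raise ValueError("no matrices given")
    snps = matrices[0].snps
    for m in matrices[1:]:
        if not m.snps["snp_id"].equals(snps["snp_id"]):
            raise ValueError("matrices passed to apply_qc must share a SNP list")

    pooled = np.vstack([m.haplotypes for m in matrices])
    keep = np.ones(len(snps), dtype=bool)
    removed: dict[str, int] = {}

    if qc.drop_unmapped:
        unmapped = snps["chrom"].isin(UNMAPPED_CHROMS).to_numpy() | (
            snps["pos_bp"].to_numpy() < 1
        )
        removed["unmapped"] = int((keep & unmapped).sum())
        keep &= ~unmapped
    else:
        removed["unmapped"] = 0

    obs = pooled != MISSING
    call_rate = obs.mean(axis=0)
    low_call = call_rate < qc.min_call_rate
    removed["low_call_rate"] = int((keep & low_call).sum())
    keep &= ~low_call

    with np.errstate(invalid="ignore"):
        freq = np.where(obs, pooled, 0).sum(axis=0) / obs.sum(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    low_maf = ~np.isfinite(maf) | (maf < qc.min_maf)
    removed["low_maf"] = int((keep & low_maf).sum())
    keep &= ~low_maf

    if not keep.any():
        raise ValueError("no SNPs survive QC")
    idx = np.flatnonzero(keep)
    out = [m.take_snps(idx) for m in matrices]
    for m in out:
        if m.has_missing():
            raise ValueError(
                f"population {m.population_label}: missing calls remain after "
                "QC; phased complete haplotypes are required downstream"
            )
    report = QCReport(n_input=len(snps), removed=removed, n_remaining=int(keep.sum()))
    return out, report


def make_pair(pop1: HaplotypeMatrix, pop2: HaplotypeMatrix) -> PopulationPair:
    """Restrict two QC'd populations to their shared polymorphic SNPs.

    A SNP is kept when it appears in both SNP lists and has allele-1
    frequency strictly inside (0, 1) within *each* population.  Genomic
    order (chrom, pos_bp) is preserved.
    """
    common = pop1.snps.merge(
        pop2.snps, on=SNP_COLUMNS, how="inner", validate="one_to_one"
    )["snp_id"]
    id_to_idx1 = pd.Series(np.arange(pop1.n_snps), index=pop1.snps["snp_id"])
    id_to_idx2 = pd.Series(np.arange(pop2.n_snps), index=pop2.snps["snp_id"])
    i1 = id_to_idx1.loc[common].to_numpy()
    i2 = id_to_idx2.loc[common].to_numpy()

    f1 = pop1.allele_frequencies()[i1]
    f2 = pop2.allele_frequencies()[i2]
    poly = (f1 > 0) & (f1 < 1) & (f2 > 0) & (f2 < 1)
    i1, i2 = i1[poly], i2[poly]
    if i1.size < 2:
        raise ValueError(
            f"fewer than 2 SNPs shared and polymorphic in both populations "
            f"({i1.size} found)"
        )
    m1 = pop1.take_snps(i1)
    order = np.lexsort((m1.snps["pos_bp"].to_numpy(),
                        m1.snps["chrom"].to_numpy()))
    return PopulationPair(pop1=m1.take_snps(order), pop2=pop2.take_snps(i2).take_snps(order))
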