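"""Per-SNP FST between two populations and its permutation test of panmixia.

The default estimator is Hudson's, computed from haplotype counts:

    FST = 1 - Hw / Hb

with Hw the average unbiased within-population expected heterozygosity
and Hb = p1(1-p2) + p2(1-p1) the between-population heterozygosity.
Hudson's estimator is insensitive to unequal sample sizes; negative
estimates (sampling noise around 0) are reported as computed.  A
Weir–Cockerham haploid-count estimator is available as an alternative.

The p-value comes from uniform permutation of haplotype population
labels: under panmixia the labels are exchangeable, and

    p = (1 + #{permuted FST >= observed}) / (n_permutations + 1)

which never returns 0.  Because the site statistic depends on the labels
only through the allele-1 count landing in population 1, label
permutation is drawn as the equivalent hypergeometric count (exact, and
fast enough for genome scans).  An exhaustive enumeration mode and an
individual-level permutation unit are provided for small samples and
phasing-robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .io import PopulationPair

__all__ = ["FstResult", "site_fst", "fst_panmixia_test", "hudson_fst",
           "weir_cockerham_fst", "all_site_fst"]


def hudson_fst(n1, c1, n2, c2):
    """Hudson FST from haplotype counts (vectorized).

    ``ni`` haplotypes sampled in population i, ``ci`` of them carrying
    allele 1.  NaN where the pooled sample is monomorphic.
    """
    n1 = np.asarray(n1, dtype=float)
    c1 = np.asarray(c1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    p1 = c1 / n1
    p2 = c2 / n2
    h1 = 2.0 * p1 * (1.0 - p1) * n1 / (n1 - 1.0)
    h2 = 2.0 * p2 * (1.0 - p2) * n2 / (n2 - 1.0)
    hw = 0.5 * (h1 + h2)
    hb = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 1.0 - hw / hb
    return np.where(hb > 0, out, np.nan)


def weir_cockerham_fst(n1, c1, n2, c2):
    """Weir–Cockerham theta for two populations of haploid sequences.

    Standard ANOVA estimator on haplotype (allele) counts; sensitive to
    sample-size imbalance, provided as a cross-check alternative.
    """
    n1 = np.asarray(n1, dtype=float)
    c1 = np.asarray(c1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    p1, p2 = c1 / n1, c2 / n2
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1.0)
    pbar = (c1 + c2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    # haploid data: no within-individual term
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = a / (a + b)
    return np.where((a + b) != 0, theta, np.nan)


_ESTIMATORS = {"hudson": hudson_fst, "wc": weir_cockerham_fst}


def _focal_counts(pair: PopulationPair, snp_index: int) -> tuple[int, int, int, int]:
    col1 = pair.pop1.haplotypes[:, snp_index]
    col2 = pair.pop2.haplotypes[:, snp_index]
    return col1.size, int(col1.sum()), col2.size, int(col2.sum())


def site_fst(pair: PopulationPair, snp_index: int, estimator: str = "hudson") -> float:
    """FST at one shared SNP.  Raises if the SNP is pooled-monomorphic."""
    n1, c1, n2, c2 = _focal_counts(pair, snp_index)
    if c1 + c2 in (0, n1 + n2):
        raise ValueError(f"SNP column {snp_index} is monomorphic in the pooled sample")
    return float(_ESTIMATORS[estimator](n1, c1, n2, c2))


def all_site_fst(pair: PopulationPair, estimator: str = "hudson") -> np.ndarray:
    """Vector of per-SNP FST over the whole shared SNP set."""
    h1, h2 = pair.pop1.haplotypes, pair.pop2.haplotypes
    return _ESTIMATORS[estimator](
        h1.shape[0], h1.sum(axis=0), h2.shape[0], h2.sum(axis=0)
    )


@dataclass
class FstResult:
    """Site FST with its panmixia permutation p-value."""

    snp_id: str
    fst: float
    p_value: float
    n_permutations: int
    overall_fst: float | None = None


def fst_panmixia_test(
    pair: PopulationPair,
    snp_index: int,
    n_permutations: int = 999,
    seed: int | np.random.Generator | None = None,
    estimator: str = "hudson",
    unit: str = "haplotype",
    method: str = "permutation",
    baseline_indices=None,
) -> FstResult:
    """Permutation test of the site FST against the panmixia null.

    Parameters
    ----------
    unit : {"haplotype", "individual"}
        Permute individual haplotype labels (default) or keep the two
        haplotypes of each diploid individual together (robust to
        within-individual phasing correlation).
    method : {"permutation", "exact"}
        Monte-Carlo permutation (requires ``n_permutations`` >= 99) or
        exhaustive enumeration of label assignments, feasible for small
        samples; "exact" sums hypergeometric probabilities of all
        allele-count splits, which enumerates the orbit of every label
        permutation.
    baseline_indices : sequence of int, optional
        When given, the tested statistic is the site FST minus the mean
        FST over these SNP columns (an "elevated relative to the local
        background" reading of the outlier test); the baseline is
        recomputed inside every permutation.  Only with the default
        haplotype unit and permutation method.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if baseline_indices is not None:
        if method != "permutation" or unit != "haplotype":
            raise ValueError(
                "conditioned test requires method='permutation', unit='haplotype'"
            )
        return _conditioned_test(
            pair, snp_index, np.asarray(baseline_indices, dtype=np.intp),
            n_permutations, rng, estimator,
        )
    n1, c1, n2, c2 = _focal_counts(pair, snp_index)
    if c1 + c2 in (0, n1 + n2):
        raise ValueError(f"SNP column {snp_index} is monomorphic in the pooled sample")
    est = _ESTIMATORS[estimator]
    observed = float(est(n1, c1, n2, c2))
    total = c1 + c2
    # float guard: permuted replicates of the observed split must count as >=
    thresh = observed - 1e-12

    if method == "exact":
        lo = max(0, total - n2)
        hi = min(total, n1)
        ks = np.arange(lo, hi + 1)
        stats = est(n1, ks, n2, total - ks)
        pmf = hypergeom.pmf(ks, n1 + n2, total, n1)
        if unit == "individual":
            # enumerate diploid genotype-count splits instead
            stats, pmf = _exact_individual(pair, snp_index, est, n1, n2)
        p = float(pmf[stats >= thresh].sum())
        return FstResult(
            snp_id=str(pair.snps["snp_id"].iloc[snp_index]),
            fst=observed,
            p_value=min(p, 1.0),
            n_permutations=0,
        )

    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    if unit == "haplotype":
        # label permutation <=> hypergeometric draw of pop1's allele-1 count
        c1_perm = rng.hypergeometric(total, n1 + n2 - total, n1, size=n_permutations)
        perm_stats = est(n1, c1_perm, n2, total - c1_perm)
    elif unit == "individual":
        g = _individual_dosages(pair, snp_index)
        m1 = pair.pop1.n_haplotypes // 2
        perm_stats = np.empty(n_permutations)
        for b in range(n_permutations):
            rng.shuffle(g)
            cc1 = int(g[:m1].sum())
            perm_stats[b] = est(n1, cc1, n2, total - cc1)
    else:
        raise ValueError("unit must be 'haplotype' or 'individual'")
    n_ge = int((perm_stats >= thresh).sum())
    p = (1.0 + n_ge) / (n_permutations + 1.0)
    return FstResult(
        snp_id=str(pair.snps["snp_id"].iloc[snp_index]),
        fst=observed,
        p_value=p,
        n_permutations=n_permutations,
    )


def _conditioned_test(pair, snp_index, baseline, n_permutations, rng, estimator):
    """Permutation test of site FST minus the mean FST of baseline SNPs.

    Labels are permuted jointly across the focal and baseline columns so
    the background level is re-estimated under each permuted labelling.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    est = _ESTIMATORS[estimator]
    cols = np.concatenate([[snp_index], baseline[baseline != snp_index]])
    h = np.vstack(
        [pair.pop1.haplotypes[:, cols], pair.pop2.haplotypes[:, cols]]
    ).astype(np.float64)
    n1 = pair.pop1.n_haplotypes
    n2 = pair.pop2.n_haplotypes
    n = n1 + n2

    def stats_from_counts(c1: np.ndarray) -> np.ndarray:
        # c1: (n_draws, n_cols) allele-1 counts in population 1
        f = est(n1, c1, n2, h.sum(axis=0)[None, :] - c1)
        return f[:, 0] - np.nanmean(f[:, 1:], axis=1)

    observed = float(stats_from_counts(h[:n1].sum(axis=0)[None, :])[0])
    thresh = observed - 1e-12
    # joint label permutation across columns: one 0/1 selection matrix per draw
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    sel = np.zeros((n_permutations, n))
    np.put_along_axis(sel, order[:, :n1], 1.0, axis=1)  # uniform n1-subsets
    perm_stats = stats_from_counts(sel @ h)
    n_ge = int((perm_stats >= thresh).sum())
    p = (1.0 + n_ge) / (n_permutations + 1.0)
    return FstResult(
        snp_id=str(pair.snps["snp_id"].iloc[snp_index]),
        fst=float(site_fst(pair, snp_index, estimator)),
        p_value=p,
        n_permutations=n_permutations,
    )


def _individual_dosages(pair: PopulationPair, snp_index: int) -> np.ndarray:
    col1 = pair.pop1.haplotypes[:, snp_index]
    col2 = pair.pop2.haplotypes[:, snp_index]
    g1 = col1.reshape(-1, 2).sum(axis=1)
    g2 = col2.reshape(-1, 2).sum(axis=1)
    return np.concatenate([g1, g2]).astype(np.int64)


def _exact_individual(pair, snp_index, est, n1, n2):
    """Enumerate splits of diploid dosage classes (multivariate hypergeometric)."""
    from itertools import product

    from scipy.special import comb

    g = _individual_dosages(pair, snp_index)
    counts = np.bincount(g, minlength=3)  # individuals with dosage 0,1,2
    m1 = n1 // 2
    stats, weights = [], []
    denom = comb(counts.sum(), m1)
    for k0, k1, k2 in product(
        range(counts[0] + 1), range(counts[1] + 1), range(counts[2] + 1)
    ):
        if k0 + k1 + k2 != m1:
            continue
        w = comb(counts[0], k0) * comb(counts[1], k1) * comb(counts[2], k2) / denom
        cc1 = k1 + 2 * k2
        stats.append(est(n1, cc1, n2, int(g.sum()) - cc1))
        weights.append(w)
    return np.asarray(stats), np.asarray(weights)
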