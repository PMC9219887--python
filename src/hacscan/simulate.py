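"""Two-population phased haplotype simulator for FPR / power benchmarks.

Model
-----
* Ancestral allele frequencies are drawn uniformly from a MAF band
  (default [0.05, 0.5]), and a pool of ``n_founders`` ancestral founder
  haplotypes is sampled from them.
* Both populations copy haplotypes from the *shared* founder pool, but
  each population uses its own founder-usage weights, drawn from a
  symmetric Dirichlet whose concentration is set so the expected
  allele-frequency divergence matches the Balding–Nichols law with
  parameter ``background_fst`` (mean = ancestral frequency, variance =
  F p(1-p); the Dirichlet tilt is the haploid realisation of that law,
  applied jointly to all SNPs so linked frequencies drift together as
  they do under genetic drift).  ``background_fst = 0`` makes usage
  uniform, so the two samples are exchangeable and per-SNP FST estimates
  centre on zero.
* Each haplotype copies its current founder SNP by SNP and switches to a
  freshly drawn founder with probability 1/``ld_block_snps`` per step
  (geometric blocks, mean length ``ld_block_snps``); each copied allele
  is independently replaced by a fresh ancestral-frequency draw with
  probability ``resample_prob``.  Copying gives the two structures the
  statistics live on: r^2 decaying geometrically with SNP distance, and
  shared descent among carriers of the same allele — haplotypes carrying
  a minor allele tend to descend from the few founders carrying it, so
  their HAC variance is reduced under neutrality (which is what makes
  the one-sided variance test conservative on neutral data).
* Haplotypes are i.i.d. within a population given the pool and weights,
  so the Hudson FST estimator stays unbiased at its background value.
* A divergent sweep is planted as end-state haplotype copying: in the
  swept population, a fraction ``swept_allele_freq`` of haplotypes carry
  allele 1 at the focal SNP and are copies of one template haplotype
  across ``span_snps`` SNPs around it, each copied allele independently
  reverted to a fresh population draw with probability ``deviation_prob``.
  This produces the two signatures the statistics respond to: collapsed
  HAC variance in the major-allele partition and elevated focal FST.

Physical positions sit on a uniform 1 SNP / 10 kb grid on one chromosome
so Mb-scale reporting works; all windowing is SNP-count based.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .candidate import candidate_divergence_test
from .io import HaplotypeMatrix, PopulationPair, make_pair
from .fst import all_site_fst

__all__ = [
    "SweepConfig",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_neutral",
    "simulate_sweep",
    "estimate_fpr",
    "estimate_power",
]

SNP_SPACING_BP = 10_000


@dataclass(frozen=True)
class SweepConfig:
    """Planted divergent sweep at one focal SNP."""

    focal_index: int
    swept_pop: str = "pop1"
    swept_allele_freq: float = 0.9
    deviation_prob: float = 0.05
    span_snps: int = 101

    def __post_init__(self) -> None:
        if not 0.5 < self.swept_allele_freq <= 1.0:
            raise ValueError("swept_allele_freq must lie in (0.5, 1]")
        if not 0.0 <= self.deviation_prob < 0.5:
            raise ValueError("deviation_prob must lie in [0, 0.5)")
        if self.span_snps < 1:
            raise ValueError("span_snps must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the neutral / sweep generator."""

    n_snps: int
    seed: int
    n_hap_per_pop: int = 100
    background_fst: float = 0.05
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_block_snps: int = 50
    n_founders: int = 10
    resample_prob: float = 0.1
    sweep: SweepConfig | None = None
    chrom: str = "1"
    pop_labels: tuple[str, str] = ("pop1", "pop2")

    def __post_init__(self) -> None:
        if self.n_snps < 2:
            raise ValueError("n_snps must be >= 2")
        if self.n_hap_per_pop < 4 or self.n_hap_per_pop % 2:
            raise ValueError("n_hap_per_pop must be an even integer >= 4")
        if not 0.0 <= self.background_fst < 1.0:
            raise ValueError("background_fst must lie in [0, 1)")
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.ld_block_snps < 1:
            raise ValueError("ld_block_snps must be >= 1")
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if not 0.0 <= self.resample_prob < 1.0:
            raise ValueError("resample_prob must lie in [0, 1)")
        if self.background_fst >= (1.0 - self.resample_prob) ** 2:
            raise ValueError(
                "background_fst must be below (1 - resample_prob)^2: the "
                "ancestral resampling shrinks attainable differentiation"
            )
        if self.sweep is not None:
            if not 0 <= self.sweep.focal_index < self.n_snps:
                raise IndexError("sweep focal_index out of range")
            if self.sweep.swept_pop not in self.pop_labels:
                raise ValueError("swept_pop must be one of pop_labels")


@dataclass
class SimulatedDataset:
    """A simulated PopulationPair plus its ground-truth record."""

    pair: PopulationPair
    sweep_present: bool
    focal_snp_id: str | None
    config: SimulationConfig


def _snp_table(config: SimulationConfig) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in range(config.n_snps)],
            "chrom": config.chrom,
            "pos_bp": np.arange(1, config.n_snps + 1, dtype=np.int64) * SNP_SPACING_BP,
            "allele_a": "A",
            "allele_b": "C",
        }
    )


#: usage-weight segments span this many LD block lengths; drift tilts are
#: drawn independently per segment so genome-wide differentiation averages
#: over several drift realisations instead of hanging on a single draw
WEIGHT_SEGMENT_BLOCKS = 8


def _usage_weights(config: SimulationConfig, rng: np.random.Generator):
    """Per-population, per-segment founder-usage weights (BN moments).

    A symmetric Dirichlet(alpha) tilt of the shared pool gives each
    population allele frequencies with mean equal to the pool frequency
    and between-population variance F_eff * p(1-p), where
    F_eff = 1 / (K*alpha + 1) — the Balding–Nichols first two moments
    realised at the haplotype-usage level.  Ancestral resampling at rate
    mu shrinks realised divergence by (1-mu)^2, so alpha is set from the
    adjusted target F / (1-mu)^2.  F = 0 yields exactly uniform usage,
    making the two samples exchangeable.  Weights are drawn independently
    for consecutive chromosome segments (WEIGHT_SEGMENT_BLOCKS LD blocks
    each): linked frequencies drift together locally while distant
    regions drift independently.

    Returns (segment_of_snp, weights1, weights2) with weights of shape
    (n_segments, n_founders).
    """
    k = config.n_founders
    f = config.background_fst
    seg_len = WEIGHT_SEGMENT_BLOCKS * config.ld_block_snps
    segment = np.arange(config.n_snps) // seg_len
    n_seg = int(segment[-1]) + 1
    if f == 0.0:
        w = np.full((n_seg, k), 1.0 / k)
        return segment, w, w.copy()
    # shrinkage corrections: ancestral resampling dilutes divergence by
    # (1-mu)^2, and the empirical pool variance is (1-1/K) p(1-p)
    f_adj = f / ((1.0 - config.resample_prob) ** 2 * (1.0 - 1.0 / k))
    if f_adj >= 1.0:
        raise ValueError(
            "background_fst too high for this founder pool / resampling rate"
        )
    alpha = (1.0 / f_adj - 1.0) / k
    w1 = rng.dirichlet(np.full(k, alpha), size=n_seg)
    w2 = rng.dirichlet(np.full(k, alpha), size=n_seg)
    return segment, w1, w2


def _copy_from_founders(
    founders: np.ndarray,
    weights: np.ndarray,
    segment: np.ndarray,
    p_anc: np.ndarray,
    n_hap: int,
    switch_prob: float,
    resample_prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Blockwise founder copying with ancestral resampling (vectorized).

    ``weights`` has one usage vector per chromosome segment; a fresh
    founder drawn at a switch point uses the weights of that column's
    segment.
    """
    k, n_snps = founders.shape
    switch = rng.random((n_hap, n_snps)) < switch_prob
    switch[:, 0] = True
    # inverse-CDF draw per column so segment-specific weights apply
    cum = np.cumsum(weights[segment], axis=1)  # (n_snps, k)
    u = rng.random((n_hap, n_snps))
    drawn = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    # forward-fill founder identity from the last switch point
    cols = np.arange(n_snps)[None, :]
    last_switch = np.maximum.accumulate(np.where(switch, cols, 0), axis=1)
    rows = np.arange(n_hap)[:, None]
    fid = drawn[rows, last_switch]
    h = founders[fid, cols]
    if resample_prob > 0:
        mask = rng.random((n_hap, n_snps)) < resample_prob
        fresh = (rng.random((n_hap, n_snps)) < p_anc[None, :]).astype(np.int8)
        h = np.where(mask, fresh, h)
    return h.astype(np.int8)


def _generate_matrices(config: SimulationConfig, rng: np.random.Generator):
    snps = _snp_table(config)
    p_anc = rng.uniform(config.maf_low, config.maf_high, size=config.n_snps)
    founders = (
        rng.random((config.n_founders, config.n_snps)) < p_anc[None, :]
    ).astype(np.int8)
    segment, w1, w2 = _usage_weights(config, rng)
    switch_prob = 1.0 / config.ld_block_snps
    mu = config.resample_prob
    mats, freqs = [], []
    for label, w in zip(config.pop_labels, (w1, w2)):
        h = _copy_from_founders(
            founders, w, segment, p_anc, config.n_hap_per_pop, switch_prob,
            mu, rng,
        )
        mats.append(HaplotypeMatrix(population_label=label, haplotypes=h, snps=snps))
        # expected allele-1 frequency of this population's copying process
        freqs.append((1.0 - mu) * (founders.T * w[segment]).sum(axis=1)
                     + mu * p_anc)
    return mats, tuple(freqs)


def simulate_neutral(config: SimulationConfig) -> SimulatedDataset:
    """Neutral two-population dataset; deterministic per seed.

    The returned pair is restricted (via :func:`make_pair`) to SNPs
    polymorphic in both samples, as the statistics require.
    """
    if config.sweep is not None:
        raise ValueError("neutral simulation must not carry a sweep config")
    rng = np.random.default_rng(config.seed)
    (m1, m2), _ = _generate_matrices(config, rng)
    pair = make_pair(m1, m2)
    return SimulatedDataset(pair=pair, sweep_present=False, focal_snp_id=None,
                            config=config)


def simulate_sweep(config: SimulationConfig) -> SimulatedDataset:
    """Neutral background plus a planted divergent sweep in one population."""
    sweep = config.sweep
    if sweep is None:
        raise ValueError("sweep config required")
    rng = np.random.default_rng(config.seed)
    (m1, m2), (p1, p2) = _generate_matrices(config, rng)
    mats = {m.population_label: m for m in (m1, m2)}
    target = mats[sweep.swept_pop]
    p_target = p1 if sweep.swept_pop == config.pop_labels[0] else p2

    h = target.haplotypes
    n = h.shape[0]
    n_swept = int(round(sweep.swept_allele_freq * n))
    swept_rows = rng.choice(n, size=n_swept, replace=False)
    template = h[swept_rows[0]].copy()

    half = (sweep.span_snps - 1) // 2
    lo = max(sweep.focal_index - half, 0)
    hi = min(sweep.focal_index + (sweep.span_snps - 1) - half, config.n_snps - 1)
    span = np.arange(lo, hi + 1)

    h[np.ix_(swept_rows, span)] = template[span][None, :]
    if sweep.deviation_prob > 0:
        deviate = rng.random((n_swept, span.size)) < sweep.deviation_prob
        fresh = (rng.random((n_swept, span.size)) < p_target[span][None, :]).astype(np.int8)
        block = h[np.ix_(swept_rows, span)]
        block[deviate] = fresh[deviate]
        h[np.ix_(swept_rows, span)] = block
    # focal SNP: swept haplotypes carry allele 1, the rest allele 0, so the
    # swept-allele frequency is exact and the site stays polymorphic
    h[:, sweep.focal_index] = 0
    h[swept_rows, sweep.focal_index] = 1

    pair = make_pair(mats[config.pop_labels[0]], mats[config.pop_labels[1]])
    focal_id = _snp_table(config)["snp_id"].iloc[sweep.focal_index]
    if focal_id not in set(pair.snps["snp_id"]):
        raise RuntimeError(
            "planted focal SNP became monomorphic in the unswept population; "
            "use a different seed or MAF band"
        )
    return SimulatedDataset(pair=pair, sweep_present=True,
                            focal_snp_id=str(focal_id), config=config)


# ---------------------------------------------------------------------------
# benchmarks


def _binom_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson interval for a binomial proportion."""
    alpha = 1.0 - level
    lo = beta_dist.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = beta_dist.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def _benchmark(
    config: SimulationConfig,
    n_replicates: int,
    window_sizes,
    alpha: float,
    n_permutations: int,
    mode: str,
    with_sweep: bool,
) -> pd.DataFrame:
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_replicates)
    hits = {L: 0 for L in window_sizes}
    tested = {L: 0 for L in window_sizes}
    n_failed = 0
    for child in children:
        rep_rng = np.random.default_rng(child)
        rep_seed = int(rep_rng.integers(0, 2**31 - 1))
        cfg = replace(config, seed=rep_seed)
        try:
            if with_sweep:
                ds = simulate_sweep(cfg)
                snp_id = ds.focal_snp_id
            else:
                ds = simulate_neutral(cfg)
                snp_id = str(
                    ds.pair.snps["snp_id"].iloc[
                        int(rep_rng.integers(0, ds.pair.n_snps))
                    ]
                )
            for L in window_sizes:
                res = candidate_divergence_test(
                    ds.pair, snp_id, size_snps=L, alpha=alpha,
                    n_permutations=n_permutations, seed=rep_rng, mode=mode,
                )
                tested[L] += 1
                if res.verdict == "significant":
                    hits[L] += 1
        except (ValueError, RuntimeError):
            n_failed += 1
            continue
    rows = []
    for L in window_sizes:
        k, n = hits[L], tested[L]
        rate = k / n if n else float("nan")
        lo, hi = _binom_ci(k, n) if n else (float("nan"), float("nan"))
        rows.append(
            {
                "window_size": L,
                "n_replicates": n,
                "n_significant": k,
                "rate": rate,
                "ci_low": lo,
                "ci_high": hi,
                "n_failed_replicates": n_failed,
            }
        )
    return pd.DataFrame(rows)


def estimate_fpr(
    config: SimulationConfig,
    n_replicates: int = 500,
    window_sizes=(25, 51, 125, 400),
    alpha: float = 0.05,
    n_permutations: int = 999,
    mode: str = "f",
) -> pd.DataFrame:
    """Empirical false-positive rate of the candidate test on neutral data.

    Per replicate one shared SNP is drawn uniformly as the "candidate"
    and tested at every window size; the rate column is the fraction of
    significant verdicts, with a 95% Clopper–Pearson CI.  Replicates
    whose simulation fails are logged in ``n_failed_replicates`` and
    excluded.
    """
    if config.sweep is not None:
        raise ValueError("estimate_fpr requires a neutral (sweep-free) config")
    if n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    if alpha == 0.0:
        # degenerate threshold: nothing can reject
        return _zero_table(window_sizes, n_replicates)
    return _benchmark(config, n_replicates, window_sizes, alpha,
                      n_permutations, mode, with_sweep=False)


def estimate_power(
    config: SimulationConfig,
    n_replicates: int = 200,
    window_sizes=(25, 51, 125, 400),
    alpha: float = 0.05,
    n_permutations: int = 999,
    mode: str = "f",
) -> pd.DataFrame:
    """Detection rate of the candidate test at the true planted focal SNP."""
    if config.sweep is None:
        raise ValueError("estimate_power requires a sweep config")
    if alpha == 0.0:
        return _zero_table(window_sizes, n_replicates)
    return _benchmark(config, n_replicates, window_sizes, alpha,
                      n_permutations, mode, with_sweep=True)


def _zero_table(window_sizes, n_replicates: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "window_size": list(window_sizes),
            "n_replicates": n_replicates,
            "n_significant": 0,
            "rate": 0.0,
            "ci_low": 0.0,
            "ci_high": [_binom_ci(0, n_replicates)[1]] * len(window_sizes),
            "n_failed_replicates": 0,
        }
    )


def mean_background_fst(dataset: SimulatedDataset) -> float:
    """Mean Hudson FST over the dataset's shared SNPs (calibration check)."""
    return float(np.nanmean(all_site_fst(dataset.pair)))
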