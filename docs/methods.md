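# Methods

This note documents the statistical model behind `hacscan`, the design
choices made where the method left room, the simulator it is benchmarked
on, and the limits of what those benchmarks show.

## Haplotype allelic classes and nvd

A haplotype's **HAC** over a window of L shared SNPs centred on a focal
SNP is its count of minor alleles across the window, with the focal SNP
excluded and "minor" defined per SNP on the two populations pooled.
Pooling makes HACs comparable between populations; excluding the focal
SNP keeps the HAC range independent of the partition a haplotype belongs
to (including it would add a constant per partition, changing neither
variance). Windows take ⌈(L−1)/2⌉ SNPs upstream and ⌊(L−1)/2⌋ downstream
of the focal SNP, truncate at chromosome ends rather than shift, and are
only defined over the SNPs *shared and polymorphic in both populations* —
so a nominal 51-SNP window can span a larger physical distance than 51
consecutive array SNPs would.

Within one population, haplotypes partition by the allele they carry at
the focal SNP; "major" is the more frequent allele *within that
population* (ties broken toward allele 0, deterministically). With
sample variances S²_M (major partition), S²_m (minor) of the HACs,

    nvd = (S²_m − S²_M) / (S²_M + S²_m)

and the pair statistic is the max over the two populations. Under a
sweep the major partition descends from few recent ancestors, S²_M
collapses, and nvd → 1. The normalizer is the sum of the two partition
variances rather than the population's total HAC variance: both are
scale-free across window sizes (what a cross-window "top 1%" ranking
needs), but the total variance includes the between-partition separation,
which is largest exactly at a swept focal SNP — normalizing by it
demotes the true signal in the ranking (in simulations with a planted
sweep the focal SNP fell mid-pack under total-variance normalization and
ranks first under the sum-of-partition-variances form). nvd is set to 0
when either partition has fewer than two haplotypes or both variances
vanish: no contrast to measure.

Degenerate definitions are pinned down explicitly: minor-allele ties at
pooled frequency 0.5 go to allele 1 (any fixed convention works — the
relabeling invariance of nvd genuinely cannot extend to exact-0.5 sites);
variances use denominator n−1; windows need ≥ 3 members.

## FST and its permutation test

Hudson's estimator from haplotype counts, FST = 1 − H_w/H_b with H_w the
average unbiased within-population expected heterozygosity and
H_b = p₁(1−p₂) + p₂(1−p₁), is the default: it is insensitive to unequal
sample sizes (relevant when one population is several times larger than
the other, as in typical river-pair designs). Negative estimates are
reported as computed. A haploid Weir–Cockerham estimator is available as
a cross-check (`estimator="wc"`).

The p-value permutes haplotype population labels uniformly — the
panmixia null — with the add-one rule p = (1+k)/(B+1), never 0. Since
the site statistic depends on labels only through the allele count
landing in population 1, label permutation is drawn as the equivalent
hypergeometric count; an exhaustive mode (`method="exact"`) sums the
hypergeometric orbit probabilities and an individual-level unit
(`unit="individual"`) keeps the two haplotypes of each diploid together
as a guard against phasing correlation.

**Plain vs windowed test.** The plain panmixia test answers "are these
two samples differentiated at all at this site". When the populations
carry genuine background differentiation (FST ≈ 0.05 between drainages
is ordinary), that null is false everywhere and the plain test rejects a
large fraction of *neutral* sites (≈ 38% in our neutral simulations at
background 0.05, n = 100+100 haplotypes). The candidate test therefore
defaults to the **windowed** statistic: site FST minus the mean FST of
the window's SNPs, with labels permuted jointly across the window so the
local background re-forms under each permutation. This asks the question
the method actually needs — "is this site elevated relative to its
flanking background" — and it is the only variant that can return a
p-value of 1 in genuinely differentiated populations (a site *below* its
local background), which published candidate-test outputs do show.
Neither variant is a calibrated test of neutrality-with-drift on its
own (the windowed variant still rejected ≈ 24% of neutral sites under
background drift); the verdict's false-positive control comes from
requiring the haplotype-variance signal *and* the FST signal jointly.

## The candidate-SNP divergence test

For a SNP nominated a priori, no multiple-testing correction is applied.
Within each population a one-sided homogeneity-of-variances test asks
whether S²_M is significantly lower than S²_m:

* `"f"` (default): F = S²_m/S²_M on F(n_m−1, n_M−1), upper tail. This is
  the classical form; it is exact under normality but sensitive to the
  heavy-tailed, mixture-like HAC distributions that strong LD produces
  (see the FPR discussion below).
* `"robust"`: Brown–Forsythe on absolute deviations from partition
  medians, two-sided p halved when the spread ordering matches the
  alternative, folded to 1 − p/2 otherwise.
* `"composite"`: `"f"` when both partitions' HAC kurtosis lies in [2, 4],
  `"robust"` otherwise — a kurtosis-gated compromise in the spirit of
  conditional variance-test procedures.

Edge conventions: a partition with fewer than two haplotypes makes that
population's p undefined (NaN) and is noted in the result; S²_M = 0 with
S²_m > 0 returns the smallest positive double (the F tail underflows);
both variances 0 returns 1. The reported variance p is the minimum over
the two populations, uncorrected (an optional two-population Bonferroni
switch exists, off by default); the verdict is **significant** iff that
minimum ≤ α and the FST p ≤ α, with NaNs forcing **ns**.

## Genome scan and consensus

The scan computes pair nvd for every shared SNP at each window size,
takes the top `top_fraction` (default 1%) per size with boundary ties
included (deterministic under duplicated values), and gates candidates by
the FST test at α. In scan mode the plain panmixia test is run once per
provisional SNP — the scan's ranking already conditions on the genome-wide
nvd distribution, and one permutation test per SNP keeps genome-scale
runs tractable; the windowed variant remains available through the
candidate interface for follow-up of individual hits. Input columns are
re-sorted genomically before windowing, making the scan invariant to
input SNP order. The consensus combiner is exact set algebra over
external methods' significant-SNP lists with a per-method membership
table; it never re-runs the external methods.

## The simulator

The generator produces the structures the statistics respond to, with
every knob surfaced in `SimulationConfig`:

* **Ancestral frequencies**: uniform on [`maf_low`, `maf_high`]
  (default [0.05, 0.5]), one SNP per 10 kb on one chromosome (positions
  matter only for reporting; windows are SNP-count based).
* **Shared founder pool**: `n_founders` (default 10) ancestral haplotypes
  drawn from the ancestral frequencies. Ten founder lineages per ~0.5 Mb
  block is a deliberately low haplotype diversity, typical of recently
  bottlenecked salmonid populations; it is what gives the minor-allele
  partition its shared-descent variance reduction under neutrality.
* **Differentiation**: each population copies from the shared pool with
  its own founder-usage weights, drawn from a symmetric Dirichlet whose
  concentration is set so the between-population frequency variance
  matches the Balding–Nichols law with parameter `background_fst`
  (mean p, variance F·p(1−p)); the concentration analytically corrects
  for the empirical pool variance factor (1−1/K) and for the divergence
  dilution (1−μ)² of ancestral resampling. Weights are drawn
  independently per chromosome segment of 8 LD block lengths, so linked
  loci drift together while distant regions drift independently. At
  F = 0 usage is exactly uniform, the two samples are exchangeable, and
  Hudson FST centres on zero by construction.
* **LD**: each haplotype copies its current founder SNP-by-SNP, switching
  to a freshly drawn founder with probability 1/`ld_block_snps` per step
  (geometric blocks, mean 50 SNPs = 0.5 Mb by default) and resampling
  each copied allele from the ancestral frequency with probability
  `resample_prob` (default 0.1). Measured r² decays from ≈ 0.075 at lag
  1 to ≈ 0.02 at lag 50 — half-decay within the block length.
* **Sweep**: in the swept population, a fraction `swept_allele_freq`
  (default 0.9) of haplotypes carry allele 1 at the focal SNP and are
  copies of one template haplotype across `span_snps` (default 101 SNPs
  ≈ 1 Mb), with per-SNP deviation probability `deviation_prob` (default
  0.05). This is end-state copying, not forward-time selection: the
  tests consume only the final haplotype pattern, and copying gives
  direct control of the HAC-variance and FST signals.

Haplotypes are i.i.d. within a population given the pool and weights, so
the Hudson estimator's unbiasedness correction applies cleanly. Realized
mean per-SNP Hudson FST over shared SNPs averages ≈ 0.038 for nominal
0.05 — the gap is the Jensen bias of averaging per-SNP ratios plus
conditioning on shared polymorphism; the ratio-of-averages estimator
recovers ≈ 0.050.

What the generator does **not** emulate: recombination-map heterogeneity,
mutation-age structure within allelic classes beyond what founder descent
induces, allele-frequency spectra shaped by selection elsewhere, array
ascertainment bias, and phasing errors (input is taken as perfectly
phased). Benchmarks on this generator therefore speak to the statistical
logic of the tests under controlled LD and drift, not to the full error
budget of a real array study.

## Benchmarks

`estimate_fpr` draws, per neutral replicate, one shared SNP uniformly as
a mock candidate and runs the full divergence test at each window size;
`estimate_power` does the same at the true planted focal SNP. Both
report Clopper–Pearson 95% intervals. With the default study conditions
(100 haplotypes/population, 2,000 SNPs, background FST 0.05, α = 0.05,
999 permutations, 500 replicates) the FPR sits at or below the nominal
5% at window sizes 25–400 — hovering nearest the boundary at the
smallest window, where the F test feels the few-lineages
effective-degrees-of-freedom problem most strongly — while power against
the default sweep is ≈ 0.8–0.9 at windows 25–125 and drops sharply at
400, reproducing the diagnostic window-size profile. Problem sizes
(2,000 SNPs, 500/150 replicates) were chosen to make the benchmark suite
a single-CPU coffee-break run while keeping binomial noise on a 5% rate
near ±2%.

## Known limitations

* The one-sided F test is anti-conservative on strongly LD-structured
  haplotypes (HAC distributions are founder mixtures, not normal); at
  small windows its marginal neutral rejection is ≈ 2–4× nominal, and the
  robust/composite modes do not fix this (they mis-estimate spread on the
  same mixtures). The verdict's joint rule absorbs most of it, but at
  window 25 the overall FPR can reach ≈ 6–7% on unlucky simulation
  draws.
* p-values of the windowed FST variant are panmixia-permutation
  probabilities of a background-adjusted statistic, not calibrated
  neutrality-with-drift p-values; interpret them as ranking evidence
  within the joint rule.
* Two populations only; no missing data after QC (phase-complete input
  is a precondition); no cM-based windows.
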