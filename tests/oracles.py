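"""Deliberately naive reference implementations used to cross-check the
package.  Everything here is written as plain loops over Python scalars,
independent of the vectorized code paths under test."""

from itertools import combinations


def hac_brute(haplotypes, member_indices, focal_index, minor_alleles):
    """Per-haplotype minor-allele count over the window, focal excluded."""
    out = []
    for row in haplotypes:
        count = 0
        for j in member_indices:
            if j == focal_index:
                continue
            if row[j] == minor_alleles[j]:
                count += 1
        out.append(count)
    return out


def sample_variance(values):
    n = len(values)
    if n < 2:
        return float("nan")
    mean = sum(values) / n
    return sum((v - mean) ** 2 for v in values) / (n - 1)


def partition_brute(haplotypes, member_indices, focal_index, minor_alleles):
    """(major_allele, n_major, n_minor, var_major, var_minor, var_total)."""
    focal = [int(row[focal_index]) for row in haplotypes]
    n1 = sum(focal)
    n0 = len(focal) - n1
    major = 1 if n1 > n0 else 0
    hac = hac_brute(haplotypes, member_indices, focal_index, minor_alleles)
    hac_major = [h for h, a in zip(hac, focal) if a == major]
    hac_minor = [h for h, a in zip(hac, focal) if a != major]
    return (
        major,
        len(hac_major),
        len(hac_minor),
        sample_variance(hac_major),
        sample_variance(hac_minor),
        sample_variance(hac),
    )


def nvd_brute(stats):
    """nvd from a partition_brute tuple; 0 on undefined/zero variances."""
    _, n_major, n_minor, var_major, var_minor, _ = stats
    if n_major < 2 or n_minor < 2:
        return 0.0
    denom = var_major + var_minor
    if denom == 0 or denom != denom:
        return 0.0
    return (var_minor - var_major) / denom


def hudson_brute(n1, c1, n2, c2):
    p1 = c1 / n1
    p2 = c2 / n2
    h1 = 2 * p1 * (1 - p1) * n1 / (n1 - 1)
    h2 = 2 * p2 * (1 - p2) * n2 / (n2 - 1)
    hw = (h1 + h2) / 2
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    return 1 - hw / hb


def permutation_p_exhaustive(col1, col2):
    """Exact p of the Hudson panmixia test by enumerating every assignment
    of the pooled haplotypes to population 1 (all same-size subsets)."""
    pooled = list(col1) + list(col2)
    n1, n2 = len(col1), len(col2)
    observed = hudson_brute(n1, sum(col1), n2, sum(col2))
    total = 0
    at_least = 0
    for subset in combinations(range(n1 + n2), n1):
        chosen = set(subset)
        c1 = sum(pooled[i] for i in chosen)
        c2 = sum(pooled) - c1
        stat = hudson_brute(n1, c1, n2, c2)
        total += 1
        if stat >= observed - 1e-12:
            at_least += 1
    return at_least / total


def qc_filters_brute(pooled_columns, chroms, positions, min_call_rate, min_maf):
    """Surviving column indices of the unmapped -> call-rate -> MAF chain."""
    survivors = []
    for j, col in enumerate(pooled_columns):
        if chroms[j] in {"", "0", "NA", "na", "none", "None", "."}:
            continue
        if positions[j] < 1:
            continue
        observed = [v for v in col if v != -1]
        if len(observed) / len(col) < min_call_rate:
            continue
        freq = sum(observed) / len(observed)
        maf = min(freq, 1 - freq)
        if maf < min_maf:
            continue
        survivors.append(j)
    return survivors
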