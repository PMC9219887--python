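import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hacscan import (
    build_window,
    hac_values,
    make_pair,
    nvd,
    partition_stats,
    pooled_minor_alleles,
)

from conftest import matrix_from, random_pair, snp_frame
from oracles import hac_brute, nvd_brute, partition_brute


class TestBuildWindow:
    def test_centred_and_truncated(self):
        snps = snp_frame(100)
        w = build_window(snps, 50, 25)
        assert w.member_indices.tolist() == list(range(38, 63))
        assert w.focal_index == 50
        # truncation at the chromosome start, no shifting
        w_edge = build_window(snps, 2, 25)
        assert w_edge.member_indices.tolist() == list(range(0, 15))

    def test_even_size_splits_upstream_heavy(self):
        snps = snp_frame(100)
        w = build_window(snps, 50, 62)
        up = (w.member_indices < 50).sum()
        down = (w.member_indices > 50).sum()
        assert (up, down) == (31, 30)

    def test_respects_chromosome_boundary(self):
        snps = snp_frame(40)
        snps.loc[20:, "chrom"] = "2"
        w = build_window(snps, 18, 25)
        assert w.member_indices.max() == 19

    def test_too_small_window_rejected(self):
        with pytest.raises(ValueError):
            build_window(snp_frame(10), 5, 2)


class TestHacValues:
    def test_all_major_haplotype_scores_zero_and_complement_max(self):
        # allele 1 is minor everywhere (frequency 0.25)
        h = np.array(
            [[0] * 7, [1] * 7, [0, 1, 0, 1, 0, 1, 0], [0] * 7], dtype=np.int8
        )
        m = matrix_from(h)
        w = build_window(m.snps, 3, 7)
        hac = hac_values(m, w)
        assert hac[0] == 0
        assert hac[1] == 6  # minor at all L-1 flanking SNPs
        assert hac.max() <= 6

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            n_hap, n_snps = 12, 7
            h = (rng.random((n_hap, n_snps)) < rng.uniform(0.2, 0.8, n_snps)).astype(
                np.int8
            )
            m = matrix_from(h)
            w = build_window(m.snps, int(rng.integers(n_snps)), 7)
            minors = np.where(m.allele_frequencies() > 0.5, 0, 1).astype(np.int8)
            expected = hac_brute(h.tolist(), w.member_indices.tolist(),
                                 w.focal_index, minors.tolist())
            np.testing.assert_array_equal(hac_values(m, w, minors), expected)


class TestPartitionStats:
    def test_identical_partition_haplotypes_give_zero_variance(self):
        h = np.vstack([[1, 1, 0, 1, 0]] * 6 + [[0, 1, 1, 0, 1], [0, 0, 0, 1, 1]])
        m = matrix_from(np.asarray(h, dtype=np.int8))
        w = build_window(m.snps, 0, 5)
        st_ = partition_stats(m, w)
        assert st_.major_allele == 1
        assert st_.var_major == 0.0

    def test_tie_broken_toward_allele_zero(self):
        # focal column (index 1) splits 2-2: major must be allele 0
        h = np.array(
            [[0, 0, 1], [1, 0, 0], [0, 1, 0], [1, 1, 1]], dtype=np.int8
        )
        m = matrix_from(h)
        st_ = partition_stats(m, build_window(m.snps, 1, 3))
        assert st_.major_allele == 0

    def test_monomorphic_focal_raises(self):
        h = np.array([[0, 1, 1], [1, 1, 0], [0, 1, 0], [1, 1, 1]], dtype=np.int8)
        m = matrix_from(h)
        with pytest.raises(ValueError, match="monomorphic"):
            partition_stats(m, build_window(m.snps, 1, 3))

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            h = (rng.random((20, 9)) < rng.uniform(0.25, 0.75, 9)).astype(np.int8)
            m = matrix_from(h)
            focal = int(rng.integers(9))
            if h[:, focal].sum() in (0, 20):
                continue
            w = build_window(m.snps, focal, 9)
            minors = np.where(m.allele_frequencies() > 0.5, 0, 1).astype(np.int8)
            got = partition_stats(m, w, minors)
            major, n_maj, n_min, v_maj, v_min, v_tot = partition_brute(
                h.tolist(), w.member_indices.tolist(), focal, minors.tolist()
            )
            assert (got.major_allele, got.n_major, got.n_minor) == (
                major, n_maj, n_min,
            )
            for a, b in ((got.var_major, v_maj), (got.var_minor, v_min),
                         (got.var_total, v_tot)):
                if np.isnan(b):
                    assert np.isnan(a)
                else:
                    assert a == pytest.approx(b)


class TestNvd:
    def test_equal_partition_variances_give_zero(self):
        # both partitions hold identical HAC multisets
        h = np.array(
            [
                [0, 0, 1, 0, 1],
                [0, 1, 0, 1, 0],
                [1, 0, 1, 0, 1],
                [1, 1, 0, 1, 0],
            ],
            dtype=np.int8,
        )
        snps = snp_frame(5)
        pair = make_pair(matrix_from(h, "A", snps), matrix_from(h.copy(), "B", snps))
        w = build_window(pair.snps, pair.snp_index("s0"), pair.n_snps)
        res = nvd(pair, w)
        assert res.nvd_pop1 == pytest.approx(0.0)
        assert res.nvd_pop2 == pytest.approx(0.0)

    def test_homogeneous_major_partition_gives_positive_nvd(self, rng):
        pair = random_pair(rng, n_hap=20, n_snps=9)
        focal = pair.n_snps // 2
        h = pair.pop1.haplotypes
        allele = 1 if h[:, focal].sum() * 2 > h.shape[0] else 0
        carriers = np.flatnonzero(h[:, focal] == allele)
        h[carriers] = h[carriers[0]]  # collapse the major partition
        w = build_window(pair.snps, focal, pair.n_snps)
        res = nvd(pair, w)
        st_ = partition_stats(pair.pop1, w, pooled_minor_alleles(pair))
        if st_.var_minor > 0:
            # collapsed major partition is the maximal sweep signature
            assert res.nvd_pop1 == pytest.approx(1.0)

    def test_pair_nvd_is_max(self, rng):
        pair = random_pair(rng)
        w = build_window(pair.snps, pair.n_snps // 2, 7)
        res = nvd(pair, w)
        assert res.pair_nvd == max(res.nvd_pop1, res.nvd_pop2)

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            pair = random_pair(rng, n_hap=16, n_snps=11)
            focal = int(rng.integers(pair.n_snps))
            w = build_window(pair.snps, focal, min(9, pair.n_snps))
            minors = pooled_minor_alleles(pair)
            res = nvd(pair, w, minors)
            for got, pop in ((res.nvd_pop1, pair.pop1), (res.nvd_pop2, pair.pop2)):
                stats = partition_brute(
                    pop.haplotypes.tolist(), w.member_indices.tolist(), focal,
                    minors.tolist(),
                )
                assert got == pytest.approx(nvd_brute(stats))

    def test_invariant_under_row_permutation(self, rng):
        pair = random_pair(rng)
        w = build_window(pair.snps, pair.n_snps // 2, 7)
        before = nvd(pair, w)
        for pop in (pair.pop1, pair.pop2):
            pop.haplotypes = pop.haplotypes[rng.permutation(pop.n_haplotypes)]
        after = nvd(pair, w)
        assert before.nvd_pop1 == pytest.approx(after.nvd_pop1)
        assert before.nvd_pop2 == pytest.approx(after.nvd_pop2)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 14))
    def test_invariant_under_allele_relabeling(self, seed, flip_col):
        """Recoding 0<->1 at a non-focal SNP and recomputing minor-allele
        definitions leaves every nvd unchanged."""
        rng = np.random.default_rng(seed)
        pair = random_pair(rng, n_hap=14, n_snps=9)
        focal = pair.n_snps // 2
        # avoid the focal column and exact-0.5 pooled frequencies, where
        # "minor" is genuinely ambiguous and no tie-break can be label-symmetric
        pooled = pair.pooled_frequencies()
        eligible = [
            j for j in range(pair.n_snps) if j != focal and pooled[j] != 0.5
        ]
        if not eligible:
            return
        col = eligible[flip_col % len(eligible)]
        w = build_window(pair.snps, focal, 7)
        before = nvd(pair, w)
        for pop in (pair.pop1, pair.pop2):
            pop.haplotypes[:, col] ^= 1
        after = nvd(pair, w)
        assert before.nvd_pop1 == pytest.approx(after.nvd_pop1)
        assert before.nvd_pop2 == pytest.approx(after.nvd_pop2)

    def test_collapsing_minor_partition_never_increases_its_variance(self, rng):
        for _ in range(10):
            pair = random_pair(rng, n_hap=20, n_snps=9)
            focal = pair.n_snps // 2
            w = build_window(pair.snps, focal, 7)
            minors = pooled_minor_alleles(pair)
            st_before = partition_stats(pair.pop1, w, minors)
            h = pair.pop1.haplotypes
            minor_rows = np.flatnonzero(
                h[:, focal] != st_before.major_allele
            )
            if minor_rows.size < 2:
                continue
            h[minor_rows] = h[minor_rows[0]]
            st_after = partition_stats(pair.pop1, w, minors)
            assert st_after.var_minor <= st_before.var_minor + 1e-12


def test_sweep_focal_nvd_exceeds_neutral_95th_percentile(sweep_dataset, rng):
    pair = sweep_dataset.pair
    minors = pooled_minor_alleles(pair)
    focal = pair.snp_index(sweep_dataset.focal_snp_id)
    w = build_window(pair.snps, focal, 25)
    focal_nvd = nvd(pair, w, minors).pair_nvd
    neutral_idx = rng.choice(
        [j for j in range(pair.n_snps) if abs(j - focal) > 100], 150, replace=False
    )
    neutral_nvds = [
        nvd(pair, build_window(pair.snps, int(j), 25), minors).pair_nvd
        for j in neutral_idx
    ]
    assert focal_nvd > np.quantile(neutral_nvds, 0.95)
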