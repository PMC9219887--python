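import numpy as np
import pytest

from hacscan import fst_panmixia_test, hudson_fst, make_pair, site_fst
from hacscan.fst import all_site_fst, weir_cockerham_fst

from conftest import matrix_from, random_pair, snp_frame
from oracles import hudson_brute, permutation_p_exhaustive


def pair_from_counts(n1, c1, n2, c2):
    """Two-population pair with given allele-1 counts at SNP 0 (plus two
    filler polymorphic SNPs so make_pair succeeds)."""
    rng = np.random.default_rng(1)

    def build(n, c, label):
        h = np.zeros((n, 3), dtype=np.int8)
        h[:c, 0] = 1
        h[: n // 2, 1] = 1
        h[:: 2, 2] = 1
        return matrix_from(h, label, snp_frame(3))

    return make_pair(build(n1, c1, "A"), build(n2, c2, "B"))


class TestSiteFst:
    def test_no_differentiation_is_near_zero(self):
        n = 200
        pair = pair_from_counts(n, n // 2, n, n // 2)
        assert abs(site_fst(pair, 0)) < 2 / n

    def test_fixed_difference_is_one(self):
        h1 = np.zeros((20, 3), dtype=np.int8)
        h1[: 10, 1] = 1
        h1[::2, 2] = 1
        h2 = h1.copy()
        h2[:, 0] = 1
        pair = make_pair(matrix_from(h1, "A"), matrix_from(h2, "B"))
        # SNP 0 is fixed 0 in A and fixed 1 in B -> dropped by make_pair;
        # evaluate on raw counts instead
        assert hudson_fst(20, 0, 20, 20) == pytest.approx(1.0)

    def test_hand_computed_hudson_value(self):
        # pop1: 12 of 20 carry allele 1; pop2: 3 of 20 — worked by hand:
        # H1 = 2*.6*.4*20/19, H2 = 2*.15*.85*20/19,
        # Hw = (H1+H2)/2 = 0.386842..., Hb = .6*.85+.15*.4 = 0.57
        expected = 1 - ((2 * 0.6 * 0.4 + 2 * 0.15 * 0.85) * (20 / 19) / 2) / 0.57
        pair = pair_from_counts(20, 12, 20, 3)
        assert site_fst(pair, 0) == pytest.approx(expected)
        assert expected == pytest.approx(0.321329639889)

    def test_matches_brute_force_randomly(self, rng):
        for _ in range(50):
            n1, n2 = int(rng.integers(4, 30)) * 2, int(rng.integers(4, 30)) * 2
            c1 = int(rng.integers(1, n1))
            c2 = int(rng.integers(1, n2))
            assert hudson_fst(n1, c1, n2, c2) == pytest.approx(
                hudson_brute(n1, c1, n2, c2)
            )

    def test_symmetric_under_population_swap(self, rng):
        pair = random_pair(rng)
        swapped = make_pair(pair.pop2, pair.pop1)
        for j in range(min(5, pair.n_snps)):
            snp = pair.snps["snp_id"].iloc[j]
            assert site_fst(pair, j) == pytest.approx(
                site_fst(swapped, swapped.snp_index(snp))
            )

    def test_monotone_in_frequency_difference(self):
        n = 100
        base = hudson_fst(n, 50, n, 50)
        values = [hudson_fst(n, 50, n, 50 + d) for d in range(0, 45, 5)]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert values[0] == pytest.approx(base)

    def test_pooled_monomorphic_raises(self):
        h = np.zeros((10, 3), dtype=np.int8)
        h[:5, 1] = 1
        h[::2, 2] = 1
        m1, m2 = matrix_from(h, "A"), matrix_from(h.copy(), "B")
        pair = make_pair(m1, m2)
        with pytest.raises(KeyError):
            pair.snp_index("s0")  # monomorphic SNPs are not even shared

    def test_weir_cockerham_close_to_hudson_at_equal_n(self):
        wc = weir_cockerham_fst(100, 70, 100, 30)
        hu = hudson_fst(100, 70, 100, 30)
        assert wc == pytest.approx(hu, abs=0.05)

    def test_all_site_fst_matches_scalar(self, rng):
        pair = random_pair(rng)
        vec = all_site_fst(pair)
        for j in range(pair.n_snps):
            assert vec[j] == pytest.approx(site_fst(pair, j))


class TestPanmixiaTest:
    def test_null_p_is_large_at_equal_frequencies(self):
        pair = pair_from_counts(40, 20, 40, 20)
        res = fst_panmixia_test(pair, 0, n_permutations=999, seed=0)
        assert res.p_value > 0.05

    def test_fixed_difference_gives_minimal_p(self):
        h1 = np.zeros((40, 3), dtype=np.int8)
        h1[:20, 1] = 1
        h1[::2, 2] = 1
        h2 = h1.copy()
        h2[:, 0] = 1
        h1[0, 0] = 1  # nearly fixed so the SNP stays shared
        h2[0, 0] = 0
        pair = make_pair(matrix_from(h1, "A"), matrix_from(h2, "B"))
        res = fst_panmixia_test(pair, 0, n_permutations=999, seed=7)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_permutation_equals_exhaustive_enumeration_4plus4(self, rng):
        for c1, c2 in [(1, 3), (2, 1), (3, 1), (1, 1), (2, 3)]:
            h1 = np.zeros((4, 3), dtype=np.int8)
            h1[:c1, 0] = 1
            h1[:2, 1] = 1
            h1[::2, 2] = 1
            h2 = np.zeros((4, 3), dtype=np.int8)
            h2[:c2, 0] = 1
            h2[:2, 1] = 1
            h2[::2, 2] = 1
            pair = make_pair(matrix_from(h1, "A"), matrix_from(h2, "B"))
            exact = fst_panmixia_test(pair, 0, method="exact").p_value
            brute = permutation_p_exhaustive(
                h1[:, 0].tolist(), h2[:, 0].tolist()
            )
            assert exact == pytest.approx(brute)
            # sampled permutation p converges to the exact orbit probability
            sampled = fst_panmixia_test(
                pair, 0, n_permutations=9999, seed=5
            ).p_value
            assert sampled == pytest.approx(brute, abs=0.02)

    def test_deterministic_given_seed(self, rng):
        pair = random_pair(rng)
        a = fst_panmixia_test(pair, 1, seed=11).p_value
        b = fst_panmixia_test(pair, 1, seed=11).p_value
        assert a == b

    def test_individual_unit_agrees_with_haplotype_unit_roughly(self, rng):
        pair = random_pair(rng, n_hap=40, n_snps=8)
        ph = fst_panmixia_test(pair, 2, n_permutations=1999, seed=3).p_value
        pi = fst_panmixia_test(
            pair, 2, n_permutations=1999, seed=3, unit="individual"
        ).p_value
        assert pi == pytest.approx(ph, abs=0.1)

    def test_conditioned_variant_detects_local_elevation_only(self, sweep_dataset):
        pair = sweep_dataset.pair
        focal = pair.snp_index(sweep_dataset.focal_snp_id)
        baseline = np.arange(focal - 12, focal + 13)
        res = fst_panmixia_test(
            pair, focal, n_permutations=499, seed=2, baseline_indices=baseline
        )
        assert res.p_value <= 0.05
        # subtracting the local background absorbs shared drift: on neutral
        # SNPs the conditioned statistic rejects no more often than the
        # plain panmixia test, which sees the genuine genome-wide
        # differentiation everywhere
        plain = cond = 0
        for j in range(focal - 700, focal - 200, 50):
            plain += (
                fst_panmixia_test(pair, j, n_permutations=499, seed=2).p_value
                <= 0.05
            )
            cond += (
                fst_panmixia_test(
                    pair, j, n_permutations=499, seed=2,
                    baseline_indices=np.arange(j - 12, j + 13),
                ).p_value
                <= 0.05
            )
        assert cond <= plain

    def test_too_few_permutations_rejected(self, rng):
        pair = random_pair(rng)
        with pytest.raises(ValueError):
            fst_panmixia_test(pair, 0, n_permutations=10, seed=1)


def test_type_i_error_controlled_under_panmixia():
    """Splitting one panmictic pool at random must not reject above nominal."""
    from hacscan import SimulationConfig, simulate_neutral

    ds = simulate_neutral(
        SimulationConfig(n_snps=700, seed=77, background_fst=0.0, ld_block_snps=1)
    )
    pair = ds.pair
    rng = np.random.default_rng(8)
    picks = rng.choice(pair.n_snps, size=500, replace=False)
    rejections = sum(
        fst_panmixia_test(pair, int(j), n_permutations=199, seed=rng).p_value <= 0.05
        for j in picks
    )
    # 95% binomial envelope around 0.05 with n=500
    assert rejections / 500 <= 0.05 + 1.645 * np.sqrt(0.05 * 0.95 / 500)
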