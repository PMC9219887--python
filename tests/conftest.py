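import numpy as np
import pandas as pd
import pytest

from hacscan import HaplotypeMatrix, PopulationPair, make_pair


def snp_frame(n, chrom="1", start_bp=10_000, spacing=10_000):
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(n)],
            "chrom": chrom,
            "pos_bp": start_bp + spacing * np.arange(n),
            "allele_a": "A",
            "allele_b": "C",
        }
    )


def matrix_from(rows, label="pop", snps=None):
    h = np.asarray(rows, dtype=np.int8)
    return HaplotypeMatrix(
        population_label=label,
        haplotypes=h,
        snps=snp_frame(h.shape[1]) if snps is None else snps,
    )


def random_pair(rng, n_hap=20, n_snps=10):
    """Small random PopulationPair; frequencies kept interior so most SNPs
    stay polymorphic in both populations."""
    while True:
        p = rng.uniform(0.2, 0.8, size=n_snps)
        h1 = (rng.random((n_hap, n_snps)) < p).astype(np.int8)
        h2 = (rng.random((n_hap, n_snps)) < p).astype(np.int8)
        snps = snp_frame(n_snps)
        try:
            return make_pair(
                matrix_from(h1, "pop1", snps), matrix_from(h2, "pop2", snps)
            )
        except ValueError:
            continue


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture(scope="session")
def neutral_dataset():
    from hacscan import SimulationConfig, simulate_neutral

    return simulate_neutral(SimulationConfig(n_snps=2000, seed=42))


@pytest.fixture(scope="session")
def sweep_dataset():
    from hacscan import SimulationConfig, SweepConfig, simulate_sweep

    return simulate_sweep(
        SimulationConfig(n_snps=2000, seed=43, sweep=SweepConfig(focal_index=1000))
    )
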