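import numpy as np
import pandas as pd
import pytest

from inbredscan.genotype import GenotypeMatrix


def make_matrix(calls, positions=None, chrom="chr1", pops=None,
                sample_ids=None, depth=None, degraded=None):
    """Small-matrix helper: calls is (n_samples, n_variants) array-like."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samp, n_var = calls.shape
    if positions is None:
        positions = np.arange(1, n_var + 1) * 1000
    if isinstance(chrom, str):
        chrom = [chrom] * n_var
    variants = pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(positions, dtype=np.int64),
        "ref": "A", "alt": "G",
    })
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n_samp)]
    if pops is None:
        pops = ["pop1"] * n_samp
    return GenotypeMatrix(sample_ids, np.array(pops, dtype=object), variants,
                          calls, depth=depth, degraded=degraded)


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(42)
    calls = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
    return make_matrix(calls)


@pytest.fixture(scope="session")
def two_pop_sim():
    """Shared small two-population simulation (no inbreeding)."""
    from inbredscan.simpop import SimConfig, sim_dataset
    cfg = SimConfig(
        pop_sizes=(("pop1", 30), ("pop2", 30)), n_chrom=2,
        chrom_length_bp=10_000_000, snp_spacing_bp=10_000,
        divergence_f=0.05, seed=123,
    )
    return sim_dataset(cfg)
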