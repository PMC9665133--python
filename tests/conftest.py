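import numpy as np
import pytest

from lriscape.genomic_io import GenomicInterval, TAD


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """One compact synthetic study shared by the slower integration tests."""
    from lriscape.synthetic import SyntheticConfig, generate_all

    cfg = SyntheticConfig(
        seed=7, n_chromosomes=1, chrom_length=10_000_000,
        n_genes_per_chrom=200, interactions_per_replicate=6_000,
        n_individuals=120, n_accessibility_samples=6,
    )
    return generate_all(cfg)


@pytest.fixture(scope="session")
def tads_chr1():
    return [
        TAD(GenomicInterval("chr1", i * 1_000_000, (i + 1) * 1_000_000), f"T{i}")
        for i in range(10)
    ]
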