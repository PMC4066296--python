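import numpy as np
import pytest

from regprio import SimulationConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic study, shared across tests."""
    cfg = SimulationConfig(
        seed=11,
        chrom_sizes={"chr1": 500_000},
        n_genes=20,
        n_pool_snps=800,
        n_fg_snps=60,
        n_samples=50,
        ld_partner_pairs=10,
        n_hic_pairs=3000,
    )
    return generate_dataset(cfg)
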