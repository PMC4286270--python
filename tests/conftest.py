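import numpy as np
import pytest

from gwis import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_subjects=300, n_snps=40, block_size=8,
                     haplotype_pool_size=6, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def planted_sim():
    """Cohort with a planted interaction at snp000005 (strong, detectable)."""
    config = SimConfig(n_subjects=400, n_snps=40, block_size=8,
                       haplotype_pool_size=8, causal_index=5,
                       beta_int_true=0.3, maf_min=0.15, seed=17)
    return simulate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
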