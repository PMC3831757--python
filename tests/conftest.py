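import pytest

from chromdiff.synthetic_data import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def study():
    """One fixed-seed synthetic study shared across tests."""
    return simulate_all(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=7, n_chrom=1, chrom_length=120_000, n_genes=10, n_tf_peaks=6,
        n_hm_peaks=6, n_false_peaks=1, n_variants=40, n_repeats=5,
    )
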