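import pytest

from starrkit.simulate import SimConfig, simulate_genome, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale study shrunk further for fast unit tests."""
    return SimConfig(
        n_chroms=2,
        chrom_length=500_000,
        n_genes=40,
        n_enhancers=8,
        n_input_frags=20_000,
        n_cdna_frags=20_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config, cell_lines=("PK15",), replicates=("rep1",))
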