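import pytest

from poease import SimConfig, simulate_reciprocal, simulate_toy_genome


@pytest.fixture(scope="session")
def toy_genome():
    """Small coding genome with 25 planted variants of known effect."""
    return simulate_toy_genome(n_genes=8, codons_per_gene=40, n_variants=25, seed=7)


@pytest.fixture(scope="session")
def small_reciprocal():
    """A quick reciprocal scenario for plumbing tests (not calibration)."""
    config = SimConfig(
        n_genes=60, depth_mean=300.0, overdispersion_rho=0.0,
        replicates_per_direction=3, seed=11,
    )
    return config, simulate_reciprocal(config)
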