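import pytest

from fltkit import sim_fixtures as sf


@pytest.fixture(scope="session")
def small_truth():
    """A small seeded synthetic experiment shared across tests."""
    return sf.simulate_genome_annotation(sf.SimConfig(seed=1, n_genes=10))


@pytest.fixture(scope="session")
def clean_truth():
    """Noise-free variant: no truncation, used by correction tests."""
    return sf.simulate_genome_annotation(
        sf.SimConfig(seed=3, n_genes=6, truncation_prob5=0.0)
    )
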