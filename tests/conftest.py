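import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_genome_and_genes():
    """A 60-kb chromosome with 25 translatable genes on both strands."""
    from xprime.simulate import simulate_genome

    rng = np.random.default_rng(7)
    return simulate_genome(rng, {"X": 60_000}, n_genes=25, mean_cds_codons=80)
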