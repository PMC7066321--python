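import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A small two-chromosome study: fast to simulate, ~180 sites."""
    from vpcontact import SimConfig

    return SimConfig(
        chrom_lengths={"chrA": 120_000, "chrB": 60_000},
        spacing=1000,
        bait_chrom="chrA",
        n_molecules=5_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Genome, restriction map and planted sites for the small study."""
    from vpcontact import make_genome

    genome, rmap, planted = make_genome(small_config)
    return genome, rmap, planted


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
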