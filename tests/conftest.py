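import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from g4dcr.io_core import ChromSizes
from g4dcr.synthetic import SimConfig, make_toy_genome, simulate_experiment

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Scaled-down study design for fast unit tests."""
    return SimConfig(
        chrom_lengths=(40_000, 30_000),
        n_g4_regions=40,
        n_dcr_bins=30,
        n_skew_regions=3,
    )


@pytest.fixture(scope="session")
def toy_world(small_config):
    """(genome, truth) for the small design, shared across tests."""
    return make_toy_genome(small_config, seed=11)


@pytest.fixture(scope="session")
def toy_experiment(small_config, toy_world):
    _, truth = toy_world
    return simulate_experiment(truth, small_config, seed=12)


@pytest.fixture()
def two_chrom_sizes() -> ChromSizes:
    return ChromSizes({"chr1": 1000, "chr2": 600})
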