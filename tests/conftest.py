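import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sstseed import Reference, SimConfig, build_index, simulate_genome, \
    simulate_reads

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def random_seq(seed: int, n: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def ref500() -> Reference:
    return Reference("ref500", random_seq(42, 500))


@pytest.fixture(scope="session")
def index500(ref500):
    return build_index(ref500, sa_sample_interval=8)


@pytest.fixture(scope="session")
def small_sim():
    """A 5 kb genome with 8x reads at 1% errors, plus its index."""
    cfg = SimConfig(genome_length=5000, coverage=8, read_length=100,
                    error_rate=0.01, rng_seed=3)
    ref = simulate_genome(cfg)
    reads = simulate_reads(ref, cfg)
    return cfg, ref, reads, build_index(ref)
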