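import pytest
from hypothesis import HealthCheck, settings

import chiatac as c
import chiatac.linker_pets as lp

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_genome():
    """1 Mb single-chromosome random genome."""
    return c.make_genome([1_000_000], seed=11)


@pytest.fixture(scope="session")
def toy_truth(toy_genome):
    """100 peaks, 40 loops with mixed anchor support on the toy genome."""
    return c.make_truth(toy_genome, n_peaks=100, n_loops=40, seed=12)


@pytest.fixture(scope="session")
def toy_pets(toy_truth, toy_genome):
    """1e5 labeled PETs from the default signal/noise mixture."""
    return c.simulate_pets(toy_truth, toy_genome, 100_000, seed=13)


@pytest.fixture(scope="session")
def toy_reads(toy_pets, toy_genome):
    """Error-free paired reads plus the junction truth table."""
    return c.simulate_reads(toy_pets, toy_genome, read_len=100, error_rate=0.0, seed=14)


@pytest.fixture(scope="session")
def recovered(toy_reads):
    """Full extraction pipeline output: (built PETs, deduplicated PETs)."""
    pairs, table = toy_reads
    named = [(r1.name.rsplit("/", 1)[0], (r1.seq, r2.seq)) for r1, r2 in pairs]
    results = lp.extract_tags_batch(named)
    tags = c.simulate.assign_truth_coordinates(results, table)
    built, _ = lp.build_pets(tags)
    return built, lp.dedup_pets(built)
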