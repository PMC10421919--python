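import pytest

from epspscnv import maplite as ml
from epspscnv import simulate as sim


@pytest.fixture(scope="session")
def small_pair():
    """Susceptible/resistant pair with a 3-unit palindromic cassette."""
    cfg = sim.SimConfig(cassette_palindromic_units=3, seed=1)
    sus, res, truth = sim.build_genomes(cfg)
    return cfg, sus, res, truth


@pytest.fixture(scope="session")
def sus_index(small_pair):
    _, sus, _, _ = small_pair
    return ml.build_index(sus)


@pytest.fixture(scope="session")
def short_reads_mapped(small_pair, sus_index):
    """5x short paired reads from the susceptible genome, mapped back to it."""
    _, sus, _, _ = small_pair
    reads = sim.simulate_reads(sus, "short_paired", 5.0, seed=2)
    recs = ml.map_reads(reads, sus_index, seed=3)
    return reads, recs
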