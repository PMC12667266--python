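import numpy as np
import pytest

from micmob.core_io import Genome
from micmob.synthgen import random_dna


@pytest.fixture(scope="session")
def bg50k():
    """A fixed 50 kb background chromosome at 33% GC."""
    rng = np.random.default_rng(1234)
    return Genome("bg50k", random_dna(rng, 50_000))


@pytest.fixture(scope="session")
def bg20k():
    rng = np.random.default_rng(99)
    return Genome("bg20k", random_dna(rng, 20_000))


@pytest.fixture(scope="session")
def island_scenario(bg50k):
    """50 kb genome with one planted island: 221 bp repeats, 12 kb span."""
    from micmob.synthgen import plant_repeat_island
    genome, truth = plant_repeat_island(bg50k, repeat_len=221,
                                        island_len=12_000, seed=7)
    return genome, truth


@pytest.fixture(scope="session")
def mmej_scenario():
    from micmob.synthgen import plant_mmej_scenario
    rng = np.random.default_rng(5)
    donor = Genome("donor", random_dna(rng, 10_000))
    recipient = Genome("recipient", random_dna(rng, 10_000))
    return plant_mmej_scenario(donor, recipient, seed=5)
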