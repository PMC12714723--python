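import numpy as np
import pytest

from adaptscan.simulate import SimulationConfig, gen_array, gen_genome


@pytest.fixture(scope="session")
def default_array():
    return gen_array(7)


@pytest.fixture(scope="session")
def small_genome():
    """A 40 kb chromosome with a 5 kb element integrated at a recorded locus."""
    cfg = SimulationConfig(seed=11, genome_lengths=(40_000,), element_length=5_000,
                           element_mode="integrated")
    replicons, element = gen_genome(cfg)
    return cfg, replicons, element


@pytest.fixture
def rng():
    return np.random.default_rng(20_240)
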