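import numpy as np
import pytest

import gxsmap as gx


@pytest.fixture(scope="session")
def small_pop():
    """A 300-animal, 40-marker HS-like population on two chromosomes."""
    founders = gx.simulate_founders(40, chrom_sizes=[50, 50], seed=11)
    return gx.simulate_hs_population(founders, 300, generations=10, seed=12)


@pytest.fixture(scope="session")
def mid_pop():
    """An 800-animal, 60-marker population on one 60-Mbp chromosome."""
    founders = gx.simulate_founders(60, chrom_sizes=[60.0], seed=21)
    return gx.simulate_hs_population(founders, 800, generations=12, seed=22)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
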