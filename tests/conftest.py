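import numpy as np
import pytest
from hypothesis import settings

import bcrphylo as bp
from bcrphylo.simulate import SimConfig, generate_repertoire_fixture

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_repertoire():
    """A small simulated repertoire under the reference parameter set,
    shared across tests that only need plausible data."""
    cfg = SimConfig(n_lineages=6, clone_size_law=("fixed", 4), n_codons=60, seed=11)
    return generate_repertoire_fixture(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_sense_codons(rng, n):
    """Random stop-free codon sequence of n codons."""
    idx = rng.integers(0, 61, size=n)
    return "".join(bp.CODON_SPACE.codons[i] for i in idx)
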