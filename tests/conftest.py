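import numpy as np
import pytest

from sgarray import simulate
from sgarray.amplicon import AmpliconReference


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def small_genome():
    """Deterministic synthetic genome with 6 multi-exon genes."""
    cfg = simulate.SimConfig(seed=7, n_genes=6)
    return simulate.simulate_genome(cfg)


@pytest.fixture
def amplicon_ref(rng):
    """A 180-nt amplicon with a 20-nt protospacer in the middle."""
    seq = random_seq(rng, 180)
    return AmpliconReference(seq, target_start=80, target_end=100)
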