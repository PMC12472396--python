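import numpy as np
import pytest

from termflex.io import Genome
from termflex.simulate import SimConfig, PlantedLocus, make_genome


@pytest.fixture
def tiny_genome():
    """The worked mapping example: 9 bp, 'GCGT' at 1-based position 3."""
    return Genome(id="tiny", seq="AAGCGTTAA")


@pytest.fixture
def random_genome():
    cfg = SimConfig(seed=7, genome_length=3000)
    return make_genome(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20250928)
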