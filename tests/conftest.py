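import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from tracksuite import GenomeDefinition, Track


@pytest.fixture
def toy_genome() -> GenomeDefinition:
    return GenomeDefinition("toy", (("chr1", 100),))


@pytest.fixture
def two_chrom_genome() -> GenomeDefinition:
    return GenomeDefinition("toy2", (("chr1", 100), ("chr2", 100)))


@pytest.fixture
def small_genome() -> GenomeDefinition:
    return GenomeDefinition("small", (("chr1", 500), ("chr2", 300)))


@pytest.fixture
def track_ab(toy_genome):
    a = Track.from_segments(toy_genome, [("chr1", 0, 30)], label="a")
    b = Track.from_segments(toy_genome, [("chr1", 20, 50)], label="b")
    return a, b


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
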