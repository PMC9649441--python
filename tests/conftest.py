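import numpy as np
import pytest

from icrdesign.core import GenomicSequence
from icrdesign.synthetic import SequenceSpec, generate_sequence

BASES = "ACGT"


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def island_3kb():
    """The acceptance-style CpG-island-like sequence: 3000 bp, GC 0.60,
    120 CpGs, clustered spacing, seed 7."""
    return generate_sequence(SequenceSpec(3000, 0.60, 120, "clustered", seed=7))


@pytest.fixture(scope="session")
def island_small():
    """Small island for fast unit tests: 400 bp, GC 0.55, 18 CpGs."""
    return generate_sequence(SequenceSpec(400, 0.55, 18, "clustered", seed=3))


@pytest.fixture(scope="session")
def amplicon_ref():
    """Amplicon-scale bisulfite reference: 300 bp, 12 CpGs."""
    return generate_sequence(SequenceSpec(300, 0.60, 12, "clustered", seed=13))


@pytest.fixture
def toy_seq():
    return GenomicSequence("toy", "ACGTACGGTACCGGTTACGA")
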