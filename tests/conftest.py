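import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from antmine import scoring
from antmine.seqio import RunConfig

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def blosum62():
    return scoring.load_matrix()


@pytest.fixture()
def config():
    """Desk-scale run configuration: short intron bounds keep windows small."""
    return RunConfig(min_intron=40, max_intron=2000)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_protein(rng, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
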