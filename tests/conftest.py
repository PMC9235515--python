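import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from alnzone.mml_core import SequencePair
from alnzone.models import AA_ORDER, AlignmentMachine, load_model


@pytest.fixture(scope="session")
def model():
    return load_model("mmlsum-like")


@pytest.fixture(scope="session")
def machine():
    return AlignmentMachine()


@pytest.fixture()
def random_pair_factory():
    """Factory for small random sequence pairs with reproducible residues."""
    aas = np.array(list(AA_ORDER))

    def make(rng, max_len=5, min_len=1):
        m = int(rng.integers(min_len, max_len + 1))
        n = int(rng.integers(min_len, max_len + 1))
        s = "".join(rng.choice(aas, m))
        t = "".join(rng.choice(aas, n))
        return SequencePair(s, t)

    return make
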