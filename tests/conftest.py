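import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from ifacecov import (PlantedCurve, SyntheticComplexSpec, load_matrix,
                      make_alignment_pool, make_complex)


@pytest.fixture(scope="session")
def blosum62():
    return load_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def small_complex():
    """One deterministic two-helix complex with a non-empty interface."""
    spec = SyntheticComplexSpec(chain_lengths=(24, 24), contact_size=5, seed=42)
    return make_complex(spec)


@pytest.fixture(scope="session")
def alignment_pool_small():
    return make_alignment_pool(PlantedCurve.constant(0.5), n=300, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
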