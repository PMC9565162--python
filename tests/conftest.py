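import numpy as np
import pytest

from crowdhop.docking import build_library
from crowdhop.fixtures import SyntheticSpec, synthetic_protein


@pytest.fixture(scope="session")
def globule20():
    return synthetic_protein(SyntheticSpec(n_residues=20, seed=7))


@pytest.fixture(scope="session")
def globule30():
    return synthetic_protein(SyntheticSpec(n_residues=30, seed=11))


@pytest.fixture(scope="session")
def globule100():
    return synthetic_protein(SyntheticSpec(n_residues=100, seed=5))


@pytest.fixture(scope="session")
def tiny_library(globule20, globule30):
    """Coarse two-type pose library, small enough for fast tests."""
    return build_library([globule20, globule30], spacing=60.0,
                         top_k=400, per_rotation=20)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
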