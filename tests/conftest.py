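import numpy as np
import pytest

from glycosite import InterfaceModel, ModelConfig
from glycosite.synthetic import ToyComplexConfig, make_toy_complex


@pytest.fixture(scope="session")
def toy_complex():
    """A deterministic 10-residue toy complex with contacts at residues 2, 3."""
    return make_toy_complex(ToyComplexConfig(seed=1))


@pytest.fixture(scope="session")
def small_model():
    """Randomly initialized desk-scale model (4 layers, scalar size 16)."""
    return InterfaceModel(ModelConfig.scaled_down(scalar_size=16, n_layers=4), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def ala_pdb(tmp_path):
    """Hand-written PDB with 3 ALA atoms."""
    text = """\
HEADER    TEST FIXTURE
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
END
"""
    path = tmp_path / "ala.pdb"
    path.write_text(text)
    return path
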