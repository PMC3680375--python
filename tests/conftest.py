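import numpy as np
import pytest

from pepmem.energetics import MembraneSpec, PoreSpec
from pepmem.params import SolvationParamTable
from pepmem.sampling import SamplingProtocol
from pepmem.structio import build_ideal_helix, place_peptide

# well-studied idealized amphipathic cationic sequence (Leu/Lys-rich)
AMPHIPATHIC_18 = "KLALKLALKALKAALKLA"

# hand-written 2-model, 3-residue PDB with one water molecule per model
PDB_TWO_MODELS = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   LYS A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  LYS A   2       3.933   2.860   0.100  1.00  0.00           C
ATOM      7  C   LYS A   2       5.450   2.750   0.200  1.00  0.00           C
ATOM      8  O   LYS A   2       6.010   1.650   0.250  1.00  0.00           O
ATOM      9  NZ  LYS A   2       3.450   3.850   2.500  1.00  0.00           N
ATOM     10  N   GLY A   3       6.100   3.900   0.300  1.00  0.00           N
ATOM     11  CA  GLY A   3       7.550   3.950   0.400  1.00  0.00           C
ATOM     12  C   GLY A   3       8.150   5.350   0.500  1.00  0.00           C
ATOM     13  O   GLY A   3       7.450   6.360   0.550  1.00  0.00           O
HETATM   14  O   HOH A 101      10.000  10.000  10.000  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       3.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   LYS A   2       4.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  LYS A   2       4.933   2.860   0.100  1.00  0.00           C
ATOM      7  C   LYS A   2       6.450   2.750   0.200  1.00  0.00           C
ATOM      8  O   LYS A   2       7.010   1.650   0.250  1.00  0.00           O
ATOM      9  NZ  LYS A   2       4.450   3.850   2.500  1.00  0.00           N
ATOM     10  N   GLY A   3       7.100   3.900   0.300  1.00  0.00           N
ATOM     11  CA  GLY A   3       8.550   3.950   0.400  1.00  0.00           C
ATOM     12  C   GLY A   3       9.150   5.350   0.500  1.00  0.00           C
ATOM     13  O   GLY A   3       8.450   6.360   0.550  1.00  0.00           O
HETATM   14  O   HOH A 101      11.000  10.000  10.000  1.00  0.00           O
ENDMDL
END
"""


@pytest.fixture(scope="session")
def table():
    return SolvationParamTable.default()


@pytest.fixture(scope="session")
def membrane():
    return MembraneSpec()


@pytest.fixture(scope="session")
def anionic_membrane():
    return MembraneSpec(anionic_fraction=0.3)


@pytest.fixture(scope="session")
def toroidal_membrane():
    return MembraneSpec(anionic_fraction=0.3, pore=PoreSpec("toroidal"))


@pytest.fixture(scope="session")
def helix18():
    return build_ideal_helix(AMPHIPATHIC_18)


@pytest.fixture(scope="session")
def placed18(helix18, membrane):
    return place_peptide(helix18, membrane, "interface")


@pytest.fixture
def tiny_protocol():
    return SamplingProtocol(n_replicas=2, n_equil_steps=200,
                            n_prod_steps=300, seed=11)


@pytest.fixture
def two_model_pdb(tmp_path):
    path = tmp_path / "two_models.pdb"
    path.write_text(PDB_TWO_MODELS)
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
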