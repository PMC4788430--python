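import numpy as np
import pytest

from tailensemble.energetics import CGEnergetics, ForceFieldParams, HarmonicTailSystem
from tailensemble.model_builder import (ScaffoldSpec, ToySystemConfig,
                                        build_tail_scaffold_system)


@pytest.fixture(scope="session")
def default_system():
    return build_tail_scaffold_system(ToySystemConfig())


@pytest.fixture(scope="session")
def small_config():
    """A 10-bead tail on a short straight scaffold -- fast to evaluate."""
    return ToySystemConfig(
        n_tail_beads=10,
        charge_pattern=(0, 1, 0, 1, 0, 0, 1, 0, 0, 1),
        scaffold_spec=ScaffoldSpec(n_positions=6, strands=2, geometry="straight"),
        seed=3,
    )


@pytest.fixture(scope="session")
def small_system(small_config):
    return build_tail_scaffold_system(small_config)


@pytest.fixture(scope="session")
def small_energetics(small_system):
    return CGEnergetics(small_system, ForceFieldParams())


@pytest.fixture
def harmonic_system():
    return HarmonicTailSystem(k=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# -- handwritten PDB fixtures -----------------------------------------------

THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.759   7.095  -4.974  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  GLY A   1       1.000   1.000   1.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       4.800   1.000   1.000  1.00  0.00           C
ENDMDL
END
"""

LYSINE_PDB = """\
ATOM      1  N   LYS A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  LYS A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB  LYS A   1       2.000   1.420   0.000  1.00  0.00           C
ATOM      4  CG  LYS A   1       3.520   1.470   0.000  1.00  0.00           C
ATOM      5  CD  LYS A   1       4.080   2.880   0.000  1.00  0.00           C
ATOM      6  CE  LYS A   1       5.600   2.930   0.000  1.00  0.00           C
ATOM      7  NZ  LYS A   1       6.150   4.300   0.000  1.00  0.00           N
ATOM      8  HZ1 LYS A   1       7.150   4.300   0.000  1.00  0.00           H
END
"""

ARGININE_PDB = """\
ATOM      1  CZ  ARG A   7       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  NH1 ARG A   7       1.330   0.000   0.000  1.00  0.00           N
ATOM      3  NH2 ARG A   7      -0.660   1.150   0.000  1.00  0.00           N
END
"""


@pytest.fixture
def three_atom_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_ATOM_PDB)
    return p


@pytest.fixture
def two_model_pdb(tmp_path):
    p = tmp_path / "two_model.pdb"
    p.write_text(TWO_MODEL_PDB)
    return p


@pytest.fixture
def lysine_pdb(tmp_path):
    p = tmp_path / "lys.pdb"
    p.write_text(LYSINE_PDB)
    return p


@pytest.fixture
def arginine_pdb(tmp_path):
    p = tmp_path / "arg.pdb"
    p.write_text(ARGININE_PDB)
    return p
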