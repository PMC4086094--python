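import numpy as np
import pytest

from tspred.depth import SolvationParams
from tspred.fixtures import make_layered_cluster
from tspred.structio import Atom, Residue, ResidueKey, Structure

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
END
"""

TRIPEPTIDE_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  VAL A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.40  0.00           C
END
"""

TWOFOLD_BIOMT = """\
REMARK 350 BIOMOLECULE: 1
REMARK 350 APPLY THE FOLLOWING TO CHAINS: A
REMARK 350   BIOMT1   1  1.000000  0.000000  0.000000        0.00000
REMARK 350   BIOMT2   1  0.000000  1.000000  0.000000        0.00000
REMARK 350   BIOMT3   1  0.000000  0.000000  1.000000        0.00000
REMARK 350   BIOMT1   2 -1.000000  0.000000  0.000000        0.00000
REMARK 350   BIOMT2   2  0.000000 -1.000000  0.000000        0.00000
REMARK 350   BIOMT3   2  0.000000  0.000000  1.000000       10.00000
"""

IDENTITY_BIOMT = """\
REMARK 350 BIOMOLECULE: 1
REMARK 350 APPLY THE FOLLOWING TO CHAINS: A
REMARK 350   BIOMT1   1  1.000000  0.000000  0.000000        0.00000
REMARK 350   BIOMT2   1  0.000000  1.000000  0.000000        0.00000
REMARK 350   BIOMT3   1  0.000000  0.000000  1.000000        0.00000
"""


def single_atom_structure(coord=(0.0, 0.0, 0.0), res_name="VAL"):
    return Structure(
        residues=[
            Residue(
                key=ResidueKey(chain_id="A", seq_num=1, res_name=res_name),
                atoms=[Atom(element="C", name="CA", coord=np.asarray(coord, float))],
            )
        ],
        source_id="single",
    )


def random_toy_structure(rng, n_atoms):
    """A blob of single-atom residues for brute-force depth oracles."""
    residues = [
        Residue(
            key=ResidueKey(chain_id="A", seq_num=i + 1, res_name="VAL"),
            atoms=[Atom(element="C", name="CA", coord=rng.uniform(-6, 6, 3))],
        )
        for i in range(n_atoms)
    ]
    return Structure(residues=residues, source_id="toy")


@pytest.fixture
def minimal_pdb():
    return MINIMAL_PDB


@pytest.fixture
def fast_solvation():
    """Few cycles and a snug box: keeps depth tests quick but exact."""
    return SolvationParams(n_cycles=2, padding=7.0, seed=7)


@pytest.fixture
def small_cluster():
    return make_layered_cluster(3, atoms_per_shell=30, shell_gap=3.2, seed=3)
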