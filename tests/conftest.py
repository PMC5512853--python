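import numpy as np
import pytest

from ppiface.structure_model import (Atom, assign_atom_classes,
                                     parse_structure)
from ppiface.synthetic_data import DimerSpec, build_toy_dimer


def make_atom(name="C", element="C", xyz=(0.0, 0.0, 0.0), radius=1.908,
              well=0.086, charge=0.0, hbclass="none", resname="ALA",
              resseq=1, chain="A"):
    return Atom(serial=1, name=name, element=element, residue_name=resname,
                residue_seq=resseq, insertion_code="", chain_id=chain,
                coord=np.asarray(xyz, dtype=float), vdw_radius=radius,
                lj_well_depth=well, charge=charge, hbond_class=hbclass)


def toy_complex(spec: DimerSpec):
    """Generate, parse and type a toy dimer in one step."""
    text = build_toy_dimer(spec)
    return assign_atom_classes(parse_structure(text, ("A", "B"),
                                               pdb_id="TOY1"))


@pytest.fixture
def default_complex():
    return toy_complex(DimerSpec(n_residues=10, n_planted_hbonds=3,
                                 n_planted_saltbridges=1,
                                 interface_contact_fraction=0.6,
                                 polarity_target="A", seed=7))


TWO_CHAIN_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       4.000   2.800   0.000  1.00  0.00           C
ATOM      7  CB  ALA A   2       5.500   2.600   0.000  1.00  0.00           C
ATOM      8  C   ALA A   2       3.600   3.700   1.200  1.00  0.00           C
ATOM      9  O   ALA A   2       3.100   3.200   2.200  1.00  0.00           O
ATOM     10  N   SER A   3       3.800   5.000   1.100  1.00  0.00           N
ATOM     11  CA  SER A   3       3.500   5.900   2.200  1.00  0.00           C
ATOM     12  OG  SER A   3       4.400   7.000   2.200  1.00  0.00           O
ATOM     13  C   SER A   3       2.100   6.500   2.100  1.00  0.00           C
ATOM     14  O   SER A   3       1.600   6.800   1.000  1.00  0.00           O
ATOM     15  N   LYS A   4       1.500   6.700   3.300  1.00  0.00           N
ATOM     16  CA  LYS A   4       0.100   7.200   3.400  1.00  0.00           C
ATOM     17  NZ  LYS A   4      -0.800   8.900   5.500  1.00  0.00           N
ATOM     18  C   LYS A   4      -0.900   6.100   3.200  1.00  0.00           C
ATOM     19  O   LYS A   4      -0.700   5.000   3.700  1.00  0.00           O
TER      20      LYS A   4
ATOM     21  N   ASP B   1      10.000   0.000   0.000  1.00  0.00           N
ATOM     22  CA  ASP B   1      11.450   0.000   0.000  1.00  0.00           C
ATOM     23  CB  ASP B   1      12.000  -1.400   0.000  1.00  0.00           C
ATOM     24  OD1 ASP B   1      13.200  -1.600   0.500  1.00  0.00           O
ATOM     25  OD2 ASP B   1      11.300  -2.400  -0.500  1.00  0.00           O
ATOM     26  C   ASP B   1      12.000   1.400   0.000  1.00  0.00           C
ATOM     27  O   ASP B   1      11.300   2.400   0.000  1.00  0.00           O
ATOM     28  N   GLY B   2      13.300   1.500   0.000  1.00  0.00           N
ATOM     29  CA  GLY B   2      14.000   2.800   0.000  1.00  0.00           C
ATOM     30  C   GLY B   2      13.600   3.700   1.200  1.00  0.00           C
ATOM     31  O   GLY B   2      13.100   3.200   2.200  1.00  0.00           O
ATOM     32  N   ARG B   3      13.800   5.000   1.100  1.00  0.00           N
ATOM     33  CA  ARG B   3      13.500   5.900   2.200  1.00  0.00           C
ATOM     34  NH1 ARG B   3      14.400   8.500   4.000  1.00  0.00           N
ATOM     35  NH2 ARG B   3      12.600   9.100   5.100  1.00  0.00           N
ATOM     36  C   ARG B   3      12.100   6.500   2.100  1.00  0.00           C
ATOM     37  O   ARG B   3      11.600   6.800   1.000  1.00  0.00           O
ATOM     38  N   GLU B   4      11.500   6.700   3.300  1.00  0.00           N
ATOM     39  CA  GLU B   4      10.100   7.200   3.400  1.00  0.00           C
ATOM     40  OE1 GLU B   4       9.100   9.300   4.600  1.00  0.00           O
ATOM     41  OE2 GLU B   4      10.600  10.100   5.600  1.00  0.00           O
ATOM     42  C   GLU B   4       9.100   6.100   3.200  1.00  0.00           C
ATOM     43  O   GLU B   4       9.300   5.000   3.700  1.00  0.00           O
TER      44      GLU B   4
END
"""


@pytest.fixture
def two_chain_pdb():
    return TWO_CHAIN_PDB
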