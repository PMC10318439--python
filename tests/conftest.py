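import numpy as np
import pytest

from glycosite.structure import compute_dihedrals
from glycosite.synthetic import FixtureSpec, make_chain, make_structure


THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.148  -4.899  1.00  0.00           C
ATOM      4  O   ALA A   1      12.376   8.345  -4.862  1.00  0.00           O
ATOM      5  CB  ALA A   1      12.252   4.678  -4.952  1.00  0.00           C
ATOM      6  N   GLY A   2      13.940   6.723  -4.752  1.00  0.00           N
ATOM      7  CA  GLY A   2      15.040   7.651  -4.506  1.00  0.00           C
ATOM      8  C   GLY A   2      15.357   8.474  -5.756  1.00  0.00           C
ATOM      9  O   GLY A   2      15.331   7.943  -6.870  1.00  0.00           O
ATOM     10  N   SER A   3      15.651   9.759  -5.560  1.00  0.00           N
ATOM     11  CA  SER A   3      15.968  10.659  -6.664  1.00  0.00           C
ATOM     12  C   SER A   3      17.338  10.330  -7.253  1.00  0.00           C
ATOM     13  O   SER A   3      18.325  10.177  -6.527  1.00  0.00           O
ATOM     14  CB  SER A   3      15.937  12.113  -6.191  1.00  0.00           C
ATOM     15  OG  SER A   3      14.649  12.447  -5.692  1.00  0.00           O
TER
END
"""

GLC_PDB = THREE_RESIDUE_PDB.replace("TER\nEND\n", """\
TER
HETATM   16  C1  GLC B   1      20.000  10.000  -6.000  1.00  0.00           C
HETATM   17  C2  GLC B   1      21.400  10.000  -6.000  1.00  0.00           C
HETATM   18  C3  GLC B   1      22.100  11.200  -6.000  1.00  0.00           C
HETATM   19  C4  GLC B   1      21.400  12.400  -6.000  1.00  0.00           C
HETATM   20  C5  GLC B   1      20.000  12.400  -6.000  1.00  0.00           C
HETATM   21  O5  GLC B   1      19.300  11.200  -6.000  1.00  0.00           O
END
""")


@pytest.fixture(scope="session")
def three_residue_pdb():
    return THREE_RESIDUE_PDB


@pytest.fixture(scope="session")
def glc_pdb():
    return GLC_PDB


@pytest.fixture(scope="session")
def helix_structure():
    """40-residue helix with one planted 4-residue site (session-cached)."""
    st, labels = make_structure(FixtureSpec(n_residues=40, geometry="helix",
                                            site_size=4, seed=7))
    return st, labels


@pytest.fixture(scope="session")
def bare_helix():
    return make_chain(FixtureSpec(n_residues=30, geometry="helix", seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation_matrix(rng):
    """Uniform random proper rotation (for rigid-transform tests)."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture(scope="session")
def trio_structures():
    """Three small structures with planted sites (shared across tests)."""
    specs = [(40, "helix", 1), (50, "extended", 2), (45, "random-coil", 3)]
    out = []
    for n, g, s in specs:
        st, labels = make_structure(FixtureSpec(n_residues=n, geometry=g,
                                                site_size=3, seed=s))
        compute_dihedrals(st)
        out.append((st, labels))
    return out
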