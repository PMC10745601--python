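import numpy as np
import pytest

from heterodta import structio
from heterodta.featurize import featurize_entries
from heterodta.synthdata import SynthSpec, generate_dataset

# -- small text fixtures -----------------------------------------------------

PDB_AGV = """\
ATOM      1  N   ALA A   1       0.000   1.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  VAL A   3       7.600   0.000   0.000  1.00  0.00           C
HETATM    5  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O
TER
END
"""

PDB_MISSING_CA = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  N   GLY A   2       3.800   0.000   0.000  1.00  0.00           N
ATOM      3  CA  VAL A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""

PDB_MSE = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  MSE A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  VAL A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""

# Ethanol CH3-CH2-OH with explicit hydrogens: 9 atoms, 8 bonds.
SDF_ETHANOL = """\
ethanol
  fixture
 comment
  9  8  0  0  0  0  0  0  0  0999 V2000
   -0.7560    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.7560    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2800    1.3300    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1500    0.5000    0.9000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1500    0.5000   -0.9000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -1.1500   -1.0300    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.1300   -0.5200    0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.1300   -0.5200   -0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
    2.2400    1.2600    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
  1  4  1  0
  1  5  1  0
  1  6  1  0
  2  7  1  0
  2  8  1  0
  3  9  1  0
M  END
$$$$
"""

MOL2_ETHANOL = """\
@<TRIPOS>MOLECULE
ethanol
 9 8 0 0 0
SMALL
GASTEIGER
@<TRIPOS>ATOM
      1 C1         -0.7560    0.0000    0.0000 C.3     1  ETH1        0.0000
      2 C2          0.7560    0.0000    0.0000 C.3     1  ETH1        0.0000
      3 O1          1.2800    1.3300    0.0000 O.3     1  ETH1        0.0000
      4 H1         -1.1500    0.5000    0.9000 H       1  ETH1        0.0000
      5 H2         -1.1500    0.5000   -0.9000 H       1  ETH1        0.0000
      6 H3         -1.1500   -1.0300    0.0000 H       1  ETH1        0.0000
      7 H4          1.1300   -0.5200    0.8900 H       1  ETH1        0.0000
      8 H5          1.1300   -0.5200   -0.8900 H       1  ETH1        0.0000
      9 H6          2.2400    1.2600    0.0000 H       1  ETH1        0.0000
@<TRIPOS>BOND
     1    1    2 1
     2    2    3 1
     3    1    4 1
     4    1    5 1
     5    1    6 1
     6    2    7 1
     7    2    8 1
     8    3    9 1
"""

PSSM_FIXTURE = """\

Last position-specific scoring matrix computed, weighted observed percentages rounded down
            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
    1 M    -2  -2  -3  -4  -2  -1  -3  -4  -2   1   2  -2   8   0  -3  -2  -1  -2  -2   1
    2 K    -1   3   0  -1  -4   1   1  -2  -1  -3  -3   5  -2  -4  -1   0  -1  -4  -2  -3
"""

HHM_FIXTURE = """\
HHsearch 1.5
NAME  fixture
LENG  3
HMM    A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
       M->M	M->I	M->D	I->M	I->I	D->M	D->D	Neff	Neff_I	Neff_D
       0	*	*	0	*	0	*	*	*	*
M 1	1000	2000	3000	1000	1000	1000	1000	1000	1000	1000	1000	1000	1000	1000	1000	1000	1000	1000	1000	1000	1
       0	*	*	*	*	*	*	1000	0	0
K 2	*	*	*	*	*	*	*	*	*	*	*	*	*	*	*	*	*	*	*	*	2
       0	*	*	*	*	*	*	1000	0	0
V 3	0	*	*	*	*	*	*	*	*	*	*	*	*	*	*	*	*	*	*	*	3
       0	*	*	*	*	*	*	1000	0	0
//
"""


@pytest.fixture()
def pdb_agv(tmp_path):
    p = tmp_path / "agv.pdb"
    p.write_text(PDB_AGV)
    return p


@pytest.fixture()
def sdf_ethanol(tmp_path):
    p = tmp_path / "ethanol.sdf"
    p.write_text(SDF_ETHANOL)
    return p


@pytest.fixture()
def mol2_ethanol(tmp_path):
    p = tmp_path / "ethanol.mol2"
    p.write_text(MOL2_ETHANOL)
    return p


# -- shared synthetic datasets (session-scoped: generation is seeded) --------

@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """16 synthetic complexes, featurized; used by training-related tests."""
    out = tmp_path_factory.mktemp("synth16")
    manifest = generate_dataset(SynthSpec(n_complexes=16, seed=3), out)
    entries = structio.read_manifest(manifest)
    return featurize_entries(entries)


@pytest.fixture(scope="session")
def tiny_manifest(tmp_path_factory):
    """A small on-disk dataset for CLI tests (8 complexes)."""
    out = tmp_path_factory.mktemp("synth8")
    return generate_dataset(SynthSpec(n_complexes=8, seed=5), out)


@pytest.fixture(scope="session")
def tiny_samples(tiny_manifest):
    return featurize_entries(structio.read_manifest(tiny_manifest))


def numeric_grad(fn, param, indices, eps=1e-6):
    """Central-difference gradient of scalar fn at selected flat indices."""
    grads = {}
    flat = param.data.ravel()
    for idx in indices:
        orig = flat[idx]
        flat[idx] = orig + eps
        hi = fn()
        flat[idx] = orig - eps
        lo = fn()
        flat[idx] = orig
        grads[idx] = (hi - lo) / (2 * eps)
    return grads


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
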