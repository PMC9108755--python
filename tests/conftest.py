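import numpy as np
import pytest

from psnvaria.fixtures import EnsembleSpec, generate_ensemble
from psnvaria.psn_core import build_norm_table, build_psn

PDB_THREE_RES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.800   1.200  1.00  0.00           C
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      9  O   GLY A   2       6.030   1.581   0.000  1.00  0.00           O
ATOM     10  N   SER A   3       6.224   3.812   0.000  1.00  0.00           N
ATOM     11  CA  SER A   3       7.683   3.810   0.000  1.00  0.00           C
ATOM     12  C   SER A   3       8.246   5.227   0.000  1.00  0.00           C
ATOM     13  O   SER A   3       7.507   6.211   0.000  1.00  0.00           O
ATOM     14  OG  SER A   3       8.210   3.100   1.120  1.00  0.00           O
HETATM   15  O   HOH A 101      10.000  10.000  10.000  1.00  0.00           O
TER
END
"""

PDB_ALTLOC = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  CB ASER A   2       5.000   0.000   0.000  0.60  0.00           C
ATOM      5  CB BSER A   2       6.000   0.000   0.000  0.40  0.00           C
ATOM      6  N   SER A   2       4.000   1.000   0.000  1.00  0.00           N
ATOM      7  CA  SER A   2       4.500   2.000   0.000  1.00  0.00           C
ATOM      8  C   SER A   2       5.500   3.000   0.000  1.00  0.00           C
TER
END
"""


@pytest.fixture
def three_res_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(PDB_THREE_RES)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(PDB_ALTLOC)
    return path


@pytest.fixture(scope="session")
def helix20():
    """Single 20-residue ideal-helix conformer."""
    return generate_ensemble(EnsembleSpec(n_residues=20, n_conformers=2,
                                          mode="none", seed=7))[0]


@pytest.fixture(scope="session")
def sidechain_ensemble():
    """Five 30-residue conformers differing only in sidechain torsions."""
    return generate_ensemble(EnsembleSpec(n_residues=30, n_conformers=5,
                                          mode="sidechain_only", seed=11))


@pytest.fixture(scope="session")
def sidechain_psns(sidechain_ensemble):
    table = build_norm_table(sidechain_ensemble)
    return [build_psn(s, table) for s in sidechain_ensemble], table


def random_psn(n, seed, density=0.3):
    """Random symmetric PSN-like graph for property tests."""
    from psnvaria.psn_core import PSNGraph

    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=2)
    mask = rng.random(iu[0].size) < density
    vals = rng.random(iu[0].size) * mask
    w[iu] = vals
    w += w.T
    labels = tuple((i, str(i + 1), "ALA") for i in range(n))
    return PSNGraph(labels=labels, weights=w, source_id=f"rand{seed}")
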