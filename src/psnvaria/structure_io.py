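"""Read protein coordinates into a uniform single-chain model.

All downstream analyses (network construction, spectral comparison,
solvent accessibility, ensemble statistics) consume the
:class:`ProteinStructure` produced here.  The reader is deliberately
strict: one chain, first model, standard amino acids only, heavy atoms
only, one alternate location per residue.  Conformers of the same
protein are assumed sequence-identical, so residue correspondence is
positional and backbone divergence is the Kabsch superposition RMSD
over all matched C-alpha atoms.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "ProteinStructure",
    "read_pdb",
    "write_pdb",
    "calpha_coords",
    "match_conformers",
    "kabsch_rmsd",
]

#: Three-letter codes of the 20 standard amino acids.
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL".split()
)

_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclasses.dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: name, element symbol, Cartesian coordinates in A."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if self.element.upper() in _HYDROGEN_ELEMENTS:
            raise ValueError(f"atom {self.name!r}: hydrogens are excluded from the model")


@dataclasses.dataclass(frozen=True)
class ResidueRecord:
    """One standard amino-acid residue with its heavy atoms.

    ``seq_index`` is the 0-based position in the chain used internally;
    ``resnum`` is the author residue number (plus insertion code) used in
    all human-facing output.
    """

    seq_index: int
    resnum: str
    resname: str
    atoms: tuple[AtomRecord, ...]

    def __post_init__(self) -> None:
        if self.resname not in STANDARD_RESIDUES:
            raise ValueError(f"residue {self.resnum}: {self.resname!r} is not a standard amino acid")
        if not self.atoms:
            raise ValueError(f"residue {self.resnum} {self.resname}: no atoms")
        n_ca = sum(1 for a in self.atoms if a.name == "CA")
        if n_ca > 1:
            raise ValueError(f"residue {self.resnum} {self.resname}: multiple CA atoms")
        object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def calpha(self) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == "CA":
                return a
        return None

    def atom_coords(self) -> np.ndarray:
        """(n_atoms, 3) array of heavy-atom coordinates."""
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclasses.dataclass(frozen=True)
class ProteinStructure:
    """An ordered single chain of residues — the unit every analysis consumes."""

    source_id: str
    chain_id: str
    residues: tuple[ResidueRecord, ...]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.source_id}: structure has no residues")
        idx = [r.seq_index for r in self.residues]
        if idx != sorted(set(idx)):
            raise ValueError(f"{self.source_id}: residues must be ordered with unique seq_index")
        object.__setattr__(self, "residues", tuple(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> tuple[str, ...]:
        return tuple(r.resname for r in self.residues)


def read_pdb(path: str | os.PathLike, chain: str | None = None,
             model: int | None = None) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Keeps ATOM records of standard amino acids in one chain of one model;
    hydrogens, waters and HETATM groups (cofactors, ligands) are dropped.
    MSE (selenomethionine) is read as MET.  For alternate locations the
    altloc with the highest summed occupancy in the residue is kept
    (first encountered wins a tie); blank-altloc atoms are always kept.

    Parameters
    ----------
    path:
        PDB-format file.
    chain:
        Chain identifier.  May be omitted when the file contains exactly
        one chain with standard amino-acid residues.
    model:
        1-based model number; defaults to the first model.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    if model is None:
        gmodel = st[0]
    else:
        matches = [m for m in st if m.num == model]
        if not matches:
            raise ValueError(f"{path}: model {model} not present")
        gmodel = matches[0]

    candidates = [ch for ch in gmodel if _has_standard_residue(ch)]
    if chain is None:
        if len(candidates) == 1:
            gchain = candidates[0]
        elif not candidates:
            raise ValueError(f"{path}: no chain with standard amino-acid residues")
        else:
            names = ", ".join(ch.name for ch in candidates)
            raise ValueError(f"{path}: ambiguous chain (candidates: {names}); pass chain=")
    else:
        matches = [ch for ch in gmodel if ch.name == chain]
        if not matches:
            raise ValueError(f"{path}: chain {chain!r} not present")
        gchain = matches[0]

    residues = []
    for gres in gchain:
        resname = gres.name
        if resname == "MSE":
            resname = "MET"
        if resname not in STANDARD_RESIDUES:
            continue  # waters, cofactors, modified residues
        atoms = _filter_atoms(gres, resname)
        if not atoms:
            continue
        resnum = f"{gres.seqid.num}{gres.seqid.icode}".strip()
        residues.append(
            ResidueRecord(seq_index=len(residues), resnum=resnum,
                          resname=resname, atoms=tuple(atoms))
        )
    if not residues:
        raise ValueError(f"{path}: zero standard residues after filtering chain {gchain.name!r}")
    stem = os.path.splitext(os.path.basename(path))[0]
    return ProteinStructure(source_id=stem, chain_id=gchain.name, residues=tuple(residues))


def _has_standard_residue(chain: gemmi.Chain) -> bool:
    return any(r.name in STANDARD_RESIDUES or r.name == "MSE" for r in chain)


def _filter_atoms(gres: gemmi.Residue, resname: str) -> list[AtomRecord]:
    """Heavy atoms of one residue, restricted to the dominant altloc."""
    heavy = [a for a in gres if a.element.name.upper() not in _HYDROGEN_ELEMENTS]

    def _alt(atom: gemmi.Atom) -> str:
        return "" if atom.altloc in ("\x00", " ", "") else atom.altloc

    occ_by_altloc: dict[str, float] = {}
    order: list[str] = []
    for a in heavy:
        alt = _alt(a)
        if alt:
            if alt not in occ_by_altloc:
                order.append(alt)
            occ_by_altloc[alt] = occ_by_altloc.get(alt, 0.0) + a.occ
    keep_alt = ""
    if occ_by_altloc:
        best = max(occ_by_altloc.values())
        keep_alt = next(alt for alt in order if occ_by_altloc[alt] == best)
    out = []
    for a in heavy:
        alt = _alt(a)
        if alt and alt != keep_alt:
            continue
        name = a.name
        element = a.element.name.upper()
        if resname == "MET" and name == "SE":
            name, element = "SD", "S"
        out.append(AtomRecord(name=name, element=element,
                              coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                              occupancy=a.occ, altloc=alt))
    return out


def write_pdb(s: ProteinStructure, path: str | os.PathLike) -> None:
    """Write a structure as standard single-chain PDB ATOM records."""
    lines = []
    serial = 1
    for res in s.residues:
        try:
            resnum = int(res.resnum)
            icode = " "
        except ValueError:
            resnum = int(res.resnum[:-1])
            icode = res.resnum[-1]
        for a in res.atoms:
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{'':1s}{res.resname:>3s} "
                f"{s.chain_id:1s}{resnum:4d}{icode:1s}   "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def calpha_coords(s: ProteinStructure) -> np.ndarray:
    """(n, 3) C-alpha trace in chain order; errors if any residue lacks CA."""
    coords = []
    for res in s.residues:
        ca = res.calpha
        if ca is None:
            raise ValueError(f"residue {res.resnum} {res.resname} has no CA atom")
        coords.append(ca.coords)
    return np.array(coords, dtype=float)


def match_conformers(a: ProteinStructure, b: ProteinStructure) -> list[tuple[int, int]]:
    """Positional residue correspondence between two sequence-identical conformers.

    The toolkit is defined for mutation-free, gap-free conformers of one
    protein, so any sequence difference is an input error, not something
    to align around.
    """
    if len(a) != len(b):
        raise ValueError(
            f"conformer length mismatch: {a.source_id} has {len(a)} residues, "
            f"{b.source_id} has {len(b)}"
        )
    for i, (ra, rb) in enumerate(zip(a.residues, b.residues)):
        if ra.resname != rb.resname:
            raise ValueError(
                f"sequence mismatch at position {i}: "
                f"{ra.resname} ({a.source_id}) vs {rb.resname} ({b.source_id})"
            )
    return [(i, i) for i in range(len(a))]


def kabsch_rmsd(x: Sequence[Sequence[float]] | np.ndarray,
                y: Sequence[Sequence[float]] | np.ndarray) -> float:
    """RMSD after least-squares optimal rigid superposition of ``y`` onto ``x``.

    Classic Kabsch algorithm: center both point sets, take the SVD of the
    covariance and correct the rotation's determinant so no reflection is
    introduced.  Degenerate (collinear/planar) inputs remain well defined
    through the SVD convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"coordinate sets must share shape (n, 3); got {x.shape} and {y.shape}")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("coordinates must be finite")
    if np.array_equal(x, y):
        return 0.0  # identical inputs superpose exactly
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    cov = yc.T @ xc
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, 1.0, d])
    rot = u @ flip @ vt
    diff = yc @ rot - xc
    return float(np.sqrt((diff ** 2).sum() / x.shape[0]))


def dump_coords(s: ProteinStructure, path: str | os.PathLike) -> None:
    """Tabular text dump ``seq_index resnum resname x y z`` of CA coordinates."""
    ca = calpha_coords(s)
    with open(path, "w") as fh:
        fh.write("# seq_index resnum resname x y z\n")
        for res, c in zip(s.residues, ca):
            fh.write(f"{res.seq_index} {res.resnum} {res.resname} "
                     f"{c[0]:.3f} {c[1]:.3f} {c[2]:.3f}\n")
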