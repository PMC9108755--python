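"""Burial- and secondary-structure-based sub-network decomposition.

A PSN is split into three edge-disjoint sub-networks over the full node
set: edges within the first class (B-B buried, or O-O ordered), edges
within the second class (E-E exposed, or N-N non-ordered) and the
bipartite edges between classes.  Residue burial comes from a built-in
Shrake-Rupley solvent-accessible surface area: residues with relative
accessibility below 7% of their reference maximum are buried.
Secondary-structure classes can be read from STRIDE/DSSP-style label
files or assigned from backbone dihedrals as a fallback; helix and
strand count as ordered, everything else as non-ordered.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .netcompare import ComparisonResult, nds
from .psn_core import ContactNormTable, PSNGraph, build_psn
from .structure_io import ProteinStructure

__all__ = [
    "ResidueClassification",
    "SubnetworkTriple",
    "compute_rsa",
    "classify_burial",
    "read_ss_labels",
    "assign_ss_fallback",
    "decompose",
    "subnetwork_nds",
]

DEFAULT_RSA_THRESHOLD = 7.0  # percent; RSA strictly below -> buried
DEFAULT_PROBE_RADIUS = 1.4  # A, water probe
DEFAULT_SPHERE_POINTS = 960

# Chothia-type heavy-atom van der Waals radii (A)
VDW_RADII = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "SE": 1.90, "P": 1.80}
_DEFAULT_RADIUS = 1.80

# Reference maximal accessible areas (A^2) for residue X in an extended
# Ala-X-Ala tripeptide (theoretical values of Tien et al. 2013).
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

# secondary-structure letters mapping to the ordered class
_ORDERED_SS = {"H", "G", "I", "E", "B"}


@dataclasses.dataclass
class ResidueClassification:
    """Per-residue two-class labels under one scheme.

    ``scheme`` is ``"burial"`` (labels B/E) or ``"secondary_structure"``
    (labels O/N).  ``rsa`` carries the underlying relative accessibility
    (percent) when the scheme is burial.
    """

    scheme: str
    labels: tuple[str, ...]
    rsa: np.ndarray | None = None

    _CLASSES = {"burial": ("B", "E"), "secondary_structure": ("O", "N")}

    def __post_init__(self) -> None:
        if self.scheme not in self._CLASSES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        allowed = set(self._CLASSES[self.scheme])
        bad = set(self.labels) - allowed
        if bad:
            raise ValueError(f"labels {bad} invalid for scheme {self.scheme}")
        self.labels = tuple(self.labels)

    @property
    def classes(self) -> tuple[str, str]:
        return self._CLASSES[self.scheme]


@dataclasses.dataclass
class SubnetworkTriple:
    """Edge-disjoint decomposition of one PSN under one labelling."""

    within_first: PSNGraph
    within_second: PSNGraph
    bipartite: PSNGraph
    scheme: str


def sphere_points(n: int = DEFAULT_SPHERE_POINTS) -> np.ndarray:
    """Near-uniform points on the unit sphere (golden-section spiral)."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_sasa(coords: np.ndarray, radii: np.ndarray,
              probe: float = DEFAULT_PROBE_RADIUS,
              n_points: int = DEFAULT_SPHERE_POINTS) -> np.ndarray:
    """Shrake-Rupley accessible surface area (A^2) per atom.

    Each atom is expanded by the probe radius and sampled with a
    near-uniform point shell; a point counts as accessible if it lies
    outside every neighbouring expanded sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = coords.shape[0]
    pts = sphere_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.empty(n)
    for i in range(n):
        shell = coords[i] + expanded[i] * pts
        neighbors = [j for j in tree.query_ball_point(coords[i], expanded[i] + max_r)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((shell - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    return areas


def compute_rsa(s: ProteinStructure, probe: float = DEFAULT_PROBE_RADIUS,
                n_points: int = DEFAULT_SPHERE_POINTS) -> np.ndarray:
    """Relative solvent accessibility (%) per residue.

    Residue SASA (Shrake-Rupley over all heavy atoms of the chain)
    divided by the residue type's reference maximal area, times 100.
    """
    coords, radii, owner = [], [], []
    for idx, res in enumerate(s.residues):
        if res.resname not in MAX_ASA:
            raise KeyError(f"no reference area for residue type {res.resname}")
        for a in res.atoms:
            coords.append(a.coords)
            radii.append(VDW_RADII.get(a.element.upper(), _DEFAULT_RADIUS))
            owner.append(idx)
    areas = atom_sasa(np.asarray(coords), np.asarray(radii), probe, n_points)
    per_res = np.zeros(len(s.residues))
    np.add.at(per_res, np.asarray(owner), areas)
    ref = np.array([MAX_ASA[r.resname] for r in s.residues])
    return 100.0 * per_res / ref


def classify_burial(rsa: Sequence[float],
                    threshold: float = DEFAULT_RSA_THRESHOLD) -> ResidueClassification:
    """B where RSA < threshold, E otherwise (RSA == threshold counts exposed)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    rsa = np.asarray(rsa, dtype=float)
    if rsa.size == 0 or np.any(np.isnan(rsa)):
        raise ValueError("missing RSA values")
    labels = tuple("B" if v < threshold else "E" for v in rsa)
    return ResidueClassification(scheme="burial", labels=labels, rsa=rsa)


def read_ss_labels(path: str | os.PathLike, n_residues: int | None = None
                   ) -> ResidueClassification:
    """Read per-residue secondary-structure classes from a label file.

    Accepts the native tabular format ``resnum resname ss_class [rsa]``
    and raw STRIDE output (``ASG`` detail lines, class in column 6).
    Helix (H/G/I) and strand (E/B/b) letters map to ordered (O),
    everything else to non-ordered (N).
    """
    classes: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if parts[0] == "ASG":  # stride detail line
                if len(parts) < 6:
                    raise ValueError(f"{path}:{lineno}: malformed stride ASG line")
                ss = parts[5]
            elif len(parts) >= 3:
                ss = parts[2]
            elif len(parts) == 1:
                ss = parts[0]
            else:
                raise ValueError(f"{path}:{lineno}: cannot parse secondary-structure row")
            classes.append("O" if ss.upper() in _ORDERED_SS else "N")
    if n_residues is not None and len(classes) != n_residues:
        raise ValueError(
            f"{path}: {len(classes)} labels for {n_residues} residues (coverage gap)")
    return ResidueClassification(scheme="secondary_structure", labels=tuple(classes))


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle in degrees for points p0-p1-p2-p3."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    return float(np.degrees(np.arctan2(y, x)))


def _backbone(s: ProteinStructure, name: str, idx: int) -> np.ndarray:
    for a in s.residues[idx].atoms:
        if a.name == name:
            return a.coords
    raise ValueError(f"residue {s.residues[idx].resnum} lacks backbone atom {name}")


def assign_ss_fallback(s: ProteinStructure) -> ResidueClassification:
    """Dihedral-window secondary-structure assignment from backbone geometry.

    A residue is helix-like when phi in [-90, -30] and psi in [-77, -17],
    strand-like when phi in [-170, -70] and psi in [90, 180] or
    [-180, -170].  Runs of at least three consecutive in-window residues
    become ordered (O); all other residues, including chain termini
    (which lack one dihedral), are non-ordered (N).
    """
    n = len(s.residues)
    in_window = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        phi = _dihedral(_backbone(s, "C", i - 1), _backbone(s, "N", i),
                        _backbone(s, "CA", i), _backbone(s, "C", i))
        psi = _dihedral(_backbone(s, "N", i), _backbone(s, "CA", i),
                        _backbone(s, "C", i), _backbone(s, "N", i + 1))
        helix = -90 <= phi <= -30 and -77 <= psi <= -17
        strand = -170 <= phi <= -70 and (90 <= psi <= 180 or -180 <= psi <= -170)
        in_window[i] = helix or strand
    labels = ["N"] * n
    run_start = None
    for i in range(n + 1):
        if i < n and in_window[i]:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= 3:
                for j in range(run_start, i):
                    labels[j] = "O"
            run_start = None
    return ResidueClassification(scheme="secondary_structure", labels=tuple(labels))


def decompose(g: PSNGraph, c: ResidueClassification) -> SubnetworkTriple:
    """Split a PSN into within-class and bipartite sub-networks.

    All three sub-networks keep the full node set; only the edges are
    filtered, so spectral comparison of sub-networks stays well-posed
    even when the two conformers disagree on a residue's class.
    """
    if len(c.labels) != g.n_nodes:
        raise ValueError(f"{len(c.labels)} labels for {g.n_nodes} nodes")
    first, second = c.classes
    lab = np.array(c.labels)
    is_first = lab == first
    mask_ff = np.outer(is_first, is_first)
    mask_ss = np.outer(~is_first, ~is_first)
    sub = {}
    for key, mask in (("ff", mask_ff), ("ss", mask_ss), ("bi", ~mask_ff & ~mask_ss)):
        w = np.where(mask, g.weights, 0.0)
        np.fill_diagonal(w, 0.0)
        sub[key] = PSNGraph(labels=g.labels, weights=w, source_id=g.source_id)
    return SubnetworkTriple(within_first=sub["ff"], within_second=sub["ss"],
                            bipartite=sub["bi"], scheme=c.scheme)


def classify_structure(s: ProteinStructure, scheme: str,
                       rsa_threshold: float = DEFAULT_RSA_THRESHOLD,
                       probe: float = DEFAULT_PROBE_RADIUS,
                       labels_path: str | None = None) -> ResidueClassification:
    """Per-conformer residue classification for one scheme."""
    if scheme == "burial":
        return classify_burial(compute_rsa(s, probe=probe), threshold=rsa_threshold)
    if scheme == "secondary_structure":
        if labels_path is not None:
            return read_ss_labels(labels_path, n_residues=len(s))
        return assign_ss_fallback(s)
    raise ValueError(f"unknown scheme {scheme!r}")


def subnetwork_nds(a: ProteinStructure, b: ProteinStructure, table: ContactNormTable,
                   scheme: str, cutoff: float = 4.5, min_separation: int = 2,
                   rsa_threshold: float = DEFAULT_RSA_THRESHOLD,
                   ) -> dict[str, ComparisonResult]:
    """Score the three sub-network pairs of two conformers under one scheme.

    Each conformer is classified with its own labels; its sub-networks
    are built from its own classification, then scored pairwise with the
    full NDS.  Returns a dict keyed by sub-network kind, e.g.
    ``{"B-B": ..., "E-E": ..., "B-E": ...}`` for the burial scheme.
    """
    ga = build_psn(a, table, cutoff=cutoff, min_separation=min_separation)
    gb = build_psn(b, table, cutoff=cutoff, min_separation=min_separation)
    ca = classify_structure(a, scheme, rsa_threshold=rsa_threshold)
    cb = classify_structure(b, scheme, rsa_threshold=rsa_threshold)
    ta = decompose(ga, ca)
    tb = decompose(gb, cb)
    f, s2 = ca.classes
    names = {"ff": f"{f}-{f}", "ss": f"{s2}-{s2}", "bi": f"{f}-{s2}"}
    return {
        names["ff"]: nds(ta.within_first, tb.within_first),
        names["ss"]: nds(ta.within_second, tb.within_second),
        names["bi"]: nds(ta.bipartite, tb.bipartite),
    }
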