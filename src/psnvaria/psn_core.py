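"""Weighted protein structure network (PSN) construction.

Residues are nodes.  Two sequentially non-adjacent residues i, j are
connected with weight

    I_ij = (number of proximal atom pairs between i and j)
           / (highest such count observed for that amino-acid-type pair)

where a proximal atom pair is any two heavy atoms within the distance
cutoff (default 4.5 A).  The denominator table is normally computed from
the input ensemble itself; a table built on a larger corpus can be
supplied instead, in which case ratios above 1 are allowed (with a
warning) rather than clipped.
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import ProteinStructure, ResidueRecord

__all__ = [
    "ContactNormTable",
    "PSNGraph",
    "count_proximal_atoms",
    "build_norm_table",
    "build_psn",
]

DEFAULT_CUTOFF = 4.5  # A, inclusive
DEFAULT_MIN_SEPARATION = 2  # |delta seq_index| below this -> no edge


def _pair_key(resname_a: str, resname_b: str) -> tuple[str, str]:
    return (resname_a, resname_b) if resname_a <= resname_b else (resname_b, resname_a)


@dataclasses.dataclass
class ContactNormTable:
    """Symmetric map: unordered amino-acid-type pair -> highest proximal-atom count."""

    max_contacts: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        canon = {}
        for (a, b), v in self.max_contacts.items():
            if v < 1:
                raise ValueError(f"max contact count for {a}-{b} must be >= 1, got {v}")
            canon[_pair_key(a, b)] = int(v)
        self.max_contacts = canon

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return _pair_key(*pair) in self.max_contacts

    def get(self, resname_a: str, resname_b: str) -> int:
        key = _pair_key(resname_a, resname_b)
        try:
            return self.max_contacts[key]
        except KeyError:
            raise KeyError(f"no normalization entry for residue-type pair {key[0]}-{key[1]}")

    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("# aa1 aa2 max_count\n")
            for (a, b) in sorted(self.max_contacts):
                fh.write(f"{a} {b} {self.max_contacts[(a, b)]}\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "ContactNormTable":
        table: dict[tuple[str, str], int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 'aa1 aa2 max_count'")
                table[(parts[0], parts[1])] = int(parts[2])
        return cls(table)


@dataclasses.dataclass
class PSNGraph:
    """Symmetric weighted adjacency over the residues of one conformer.

    ``labels`` are (seq_index, resnum, resname) triples in chain order;
    ``weights`` is the dense n x n matrix of I_ij values.
    """

    labels: tuple[tuple[int, str, str], ...]
    weights: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.labels = tuple(tuple(l) for l in self.labels)
        w = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} does not match {n} labels")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0.0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0) or np.any(~np.isfinite(w)):
            raise ValueError("weights must be finite and non-negative")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def same_labels(self, other: "PSNGraph") -> bool:
        return self.labels == other.labels

    def edges(self) -> Iterable[tuple[int, int, float]]:
        """Nonzero upper-triangle edges as (i, j, weight), i < j."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        for i, j in zip(iu, ju):
            w = self.weights[i, j]
            if w != 0.0:
                yield int(i), int(j), float(w)

    def to_edge_list(self, path: str | os.PathLike, chain_id: str = "A") -> None:
        with open(path, "w") as fh:
            fh.write("# resA resB weight\n")
            for i, j, w in self.edges():
                _, num_i, name_i = self.labels[i]
                _, num_j, name_j = self.labels[j]
                fh.write(f"{chain_id}:{num_i}:{name_i} {chain_id}:{num_j}:{name_j} {w:.6f}\n")

    def to_matrix_tsv(self, path: str | os.PathLike) -> None:
        header = "\t".join(f"{num}:{name}" for _, num, name in self.labels)
        np.savetxt(path, self.weights, delimiter="\t", fmt="%.6f",
                   header=header, comments="# ")


def count_proximal_atoms(a: ResidueRecord, b: ResidueRecord,
                         cutoff: float = DEFAULT_CUTOFF) -> int:
    """Number of heavy-atom pairs between two residues within ``cutoff`` (inclusive)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not a.atoms or not b.atoms:
        raise ValueError("residues must carry at least one atom")
    d = cdist(a.atom_coords(), b.atom_coords())
    return int(np.count_nonzero(d <= cutoff))


def _pair_counts(s: ProteinStructure, cutoff: float,
                 min_separation: int) -> dict[tuple[int, int], int]:
    """Proximal-atom counts for every eligible residue pair of one structure.

    A coarse residue-level distance prefilter keeps the all-atom double
    loop away from pairs that cannot possibly contact.
    """
    n = len(s.residues)
    coords = [r.atom_coords() for r in s.residues]
    centers = np.array([c.mean(axis=0) for c in coords])
    radii = np.array([np.linalg.norm(c - ctr, axis=1).max()
                      for c, ctr in zip(coords, centers)])
    counts: dict[tuple[int, int], int] = {}
    for i in range(n):
        for j in range(i + min_separation, n):
            if np.linalg.norm(centers[i] - centers[j]) > radii[i] + radii[j] + cutoff:
                continue
            c = int(np.count_nonzero(cdist(coords[i], coords[j]) <= cutoff))
            if c:
                counts[(i, j)] = c
    return counts


def build_norm_table(ensemble: Sequence[ProteinStructure],
                     cutoff: float = DEFAULT_CUTOFF,
                     min_separation: int = DEFAULT_MIN_SEPARATION) -> ContactNormTable:
    """Per amino-acid-type pair, the highest proximal-atom count in the ensemble.

    Pairs never observed in contact are absent from the table.
    """
    if not ensemble:
        raise ValueError("ensemble must contain at least one structure")
    table: dict[tuple[str, str], int] = {}
    for s in ensemble:
        for (i, j), c in _pair_counts(s, cutoff, min_separation).items():
            key = _pair_key(s.residues[i].resname, s.residues[j].resname)
            if c > table.get(key, 0):
                table[key] = c
    return ContactNormTable(table)


def build_psn(s: ProteinStructure, table: ContactNormTable,
              cutoff: float = DEFAULT_CUTOFF,
              min_separation: int = DEFAULT_MIN_SEPARATION) -> PSNGraph:
    """Build the weighted PSN of one conformer.

    weight[i, j] = proximal-atom count / table max for the residue-type
    pair, for |seq_index_i - seq_index_j| >= min_separation; zero
    otherwise.  A table that lacks an occurring contact pair is an error;
    a foreign table that yields ratios above 1 triggers a warning only.
    """
    if len(s.residues) == 0:
        raise ValueError("empty structure")
    counts = _pair_counts(s, cutoff, min_separation)
    missing = sorted({
        _pair_key(s.residues[i].resname, s.residues[j].resname)
        for (i, j) in counts
        if (s.residues[i].resname, s.residues[j].resname) not in table
    })
    if missing:
        pairs = ", ".join(f"{a}-{b}" for a, b in missing)
        raise KeyError(f"normalization table missing residue-type pairs: {pairs}")
    n = len(s.residues)
    w = np.zeros((n, n))
    for (i, j), c in counts.items():
        w[i, j] = w[j, i] = c / table.get(s.residues[i].resname, s.residues[j].resname)
    if np.any(w > 1.0 + 1e-12):
        warnings.warn(
            "edge weights above 1: normalization table does not dominate this "
            "structure's contact counts (foreign table?)", stacklevel=2)
    labels = tuple((r.seq_index, r.resnum, r.resname) for r in s.residues)
    return PSNGraph(labels=labels, weights=w, source_id=s.source_id)
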