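"""Five-category classification of per-protein structural variability.

Every conformer pair of a protein contributes one scatter point
(backbone RMSD on x, network dissimilarity NDS on y).  Dataset-wide
means split the plane into four quadrants; mean + SD define the
"permissible extremity" on each axis.  A protein is assigned the first
matching category:

    R — rigid: >= 60% of all points in the rigid area (both scores below
        the mean) and no point beyond either extremity;
    N — preserved network: of the points outside the rigid area, >= 60%
        have high RMSD but low NDS, and no point exceeds the NDS
        extremity;
    B — variable network: of the non-rigid points, >= 60% have high NDS
        but low RMSD, and no point exceeds the RMSD extremity;
    F — flexible: >= 60% of the non-rigid points have both scores at or
        above the mean;
    M — mixed: anything else, including extremity violators of R/N/B.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

__all__ = ["ScatterPoint", "Thresholds", "CategoryResult",
           "dataset_thresholds", "categorize_protein"]

DEFAULT_FRACTION_CUTOFF = 0.60


@dataclasses.dataclass(frozen=True)
class ScatterPoint:
    """One conformer-pair comparison: RMSD (A) and NDS."""

    id_a: str
    id_b: str
    rmsd: float
    nds: float

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        if not 0 <= self.nds <= math.sqrt(3) + 1e-9:
            raise ValueError(f"nds={self.nds} outside [0, sqrt(3)]")


@dataclasses.dataclass(frozen=True)
class Thresholds:
    """Dataset-wide quadrant means and permissible extremities."""

    mean_rmsd: float
    sd_rmsd: float
    mean_nds: float
    sd_nds: float
    fraction_cutoff: float = DEFAULT_FRACTION_CUTOFF
    extremity_nds_override: float | None = None

    def __post_init__(self) -> None:
        for name in ("mean_rmsd", "sd_rmsd", "mean_nds", "sd_nds"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def extremity_rmsd(self) -> float:
        return self.mean_rmsd + self.sd_rmsd

    @property
    def extremity_nds(self) -> float:
        if self.extremity_nds_override is not None:
            return self.extremity_nds_override
        return self.mean_nds + self.sd_nds


@dataclasses.dataclass(frozen=True)
class CategoryResult:
    """Category assignment with the quadrant evidence that produced it."""

    category: str  # R, N, B, F or M
    n_points: int
    fraction_rigid_area: float
    fraction_by_quadrant: dict[str, float]  # over non-rigid points: N, B, F keys
    extremity_violations: tuple[str, ...]
    thresholds: Thresholds


def dataset_thresholds(points: Sequence[ScatterPoint],
                       fraction_cutoff: float = DEFAULT_FRACTION_CUTOFF,
                       extremity_nds_override: float | None = None) -> Thresholds:
    """Arithmetic mean and population SD of RMSD and NDS over all points."""
    if len(points) < 2:
        raise ValueError("need at least 2 points to compute dataset thresholds")
    rmsd = np.array([p.rmsd for p in points])
    nds = np.array([p.nds for p in points])
    return Thresholds(
        mean_rmsd=float(rmsd.mean()), sd_rmsd=float(rmsd.std()),
        mean_nds=float(nds.mean()), sd_nds=float(nds.std()),
        fraction_cutoff=fraction_cutoff,
        extremity_nds_override=extremity_nds_override,
    )


def categorize_protein(points: Sequence[ScatterPoint], t: Thresholds) -> CategoryResult:
    """Assign one of {R, N, B, F, M} to a protein's scatter.

    Rules are evaluated in the order R, N, B, F; the first one whose
    quadrant fraction and extremity conditions hold wins; otherwise the
    protein is mixed (M).  Quadrant membership at exactly the mean
    counts to the high side.
    """
    if not points:
        raise ValueError("empty point set")
    rmsd = np.array([p.rmsd for p in points])
    nds = np.array([p.nds for p in points])
    n = len(points)
    cutoff = t.fraction_cutoff

    rigid_mask = (rmsd < t.mean_rmsd) & (nds < t.mean_nds)
    frac_rigid = float(rigid_mask.mean())
    beyond_rmsd = rmsd > t.extremity_rmsd
    beyond_nds = nds > t.extremity_nds
    violations = tuple(
        f"{points[i].id_a}|{points[i].id_b}:"
        + ("rmsd" if beyond_rmsd[i] else "") + ("nds" if beyond_nds[i] else "")
        for i in np.flatnonzero(beyond_rmsd | beyond_nds)
    )

    nonrigid = ~rigid_mask
    n_nonrigid = int(nonrigid.sum())
    if n_nonrigid:
        q_n = float(((rmsd >= t.mean_rmsd) & (nds < t.mean_nds))[nonrigid].mean())
        q_b = float(((nds >= t.mean_nds) & (rmsd < t.mean_rmsd))[nonrigid].mean())
        q_f = float(((rmsd >= t.mean_rmsd) & (nds >= t.mean_nds))[nonrigid].mean())
    else:
        q_n = q_b = q_f = 0.0
    fractions = {"N": q_n, "B": q_b, "F": q_f}

    def result(cat: str) -> CategoryResult:
        return CategoryResult(category=cat, n_points=n,
                              fraction_rigid_area=frac_rigid,
                              fraction_by_quadrant=fractions,
                              extremity_violations=violations, thresholds=t)

    if frac_rigid >= cutoff and not violations:
        return result("R")
    if n_nonrigid == 0:
        # everything rigid-area but an extremity spoiled R
        return result("M")
    if q_n >= cutoff and not np.any(beyond_nds):
        return result("N")
    if q_b >= cutoff and not np.any(beyond_rmsd):
        return result("B")
    if q_f >= cutoff:
        return result("F")
    return result("M")


def write_category_table(
        rows: Sequence[tuple[str, int, int, CategoryResult, float, float]],
        path) -> None:
    """Per-protein CSV: protein, sizes, category and quadrant evidence.

    Each row is (protein, n_structures, n_pairs, result, max_rmsd, max_nds).
    """
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["protein", "n_structures", "n_pairs", "category",
                         "frac_rigid", "frac_N", "frac_B", "frac_F",
                         "max_rmsd", "max_nds"])
        for protein, n_structures, n_pairs, res, max_rmsd, max_nds in rows:
            writer.writerow([
                protein, n_structures, n_pairs, res.category,
                f"{res.fraction_rigid_area:.4f}",
                f"{res.fraction_by_quadrant['N']:.4f}",
                f"{res.fraction_by_quadrant['B']:.4f}",
                f"{res.fraction_by_quadrant['F']:.4f}",
                f"{max_rmsd:.4f}", f"{max_nds:.4f}",
            ])
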