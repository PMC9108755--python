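"""High-level driver: all-pairs comparison of a conformer ensemble.

Glue shared by the command-line interface and scripted analyses: build
the normalization table and PSNs once, cache each conformer's Laplacian
spectrum, and score every conformer pair with RMSD and NDS.
"""

from __future__ import annotations

import csv
import itertools
import os
from typing import Sequence

from .classify import ScatterPoint
from .netcompare import (ComparisonResult, correspondence_score,
                         edge_difference_score, ewcs_score, laplacian_spectrum)
from .psn_core import ContactNormTable, PSNGraph, build_norm_table, build_psn
from .structure_io import ProteinStructure, calpha_coords, kabsch_rmsd, match_conformers

__all__ = ["compare_all", "write_pairwise_csv", "read_pairwise_csv"]

import numpy as np


def compare_all(structures: Sequence[ProteinStructure],
                table: ContactNormTable | None = None,
                cutoff: float = 4.5, min_separation: int = 2,
                k: int | None = None, crs_k: int = 5) -> list[ComparisonResult]:
    """RMSD + NDS for every conformer pair of one ensemble.

    The normalization table defaults to the per-type maxima of the input
    ensemble itself.  Spectra are decomposed once per conformer, not per
    pair.
    """
    if len(structures) < 2:
        raise ValueError("need at least two conformers")
    for other in structures[1:]:
        match_conformers(structures[0], other)
    if table is None:
        table = build_norm_table(structures, cutoff=cutoff,
                                 min_separation=min_separation)
    psns = [build_psn(s, table, cutoff=cutoff, min_separation=min_separation)
            for s in structures]
    cas = [calpha_coords(s) for s in structures]
    specs = [laplacian_spectrum(g) for g in psns]
    results = []
    for i, j in itertools.combinations(range(len(structures)), 2):
        a, b = psns[i], psns[j]
        rmsd = kabsch_rmsd(cas[i], cas[j])
        if np.array_equal(a.weights, b.weights):
            results.append(ComparisonResult(eds=0.0, ewcs=0.0, crs=1.0, nds=0.0,
                                            rmsd=rmsd, id_a=a.source_id,
                                            id_b=b.source_id))
            continue
        eds = edge_difference_score(a, b)
        ewcs = ewcs_score(a, b, k=k, spec_a=specs[i], spec_b=specs[j])
        crs = correspondence_score(a, b, k=crs_k, spec_a=specs[i], spec_b=specs[j])
        score = float(np.sqrt(eds ** 2 + ewcs ** 2 + (1.0 - crs) ** 2))
        results.append(ComparisonResult(eds=eds, ewcs=ewcs, crs=crs, nds=score,
                                        rmsd=rmsd, id_a=a.source_id,
                                        id_b=b.source_id))
    return results


def to_scatter_points(results: Sequence[ComparisonResult]) -> list[ScatterPoint]:
    return [ScatterPoint(id_a=r.id_a, id_b=r.id_b, rmsd=r.rmsd, nds=r.nds)
            for r in results]


def write_pairwise_csv(results: Sequence[ComparisonResult],
                       path: str | os.PathLike,
                       header_lines: Sequence[str] = ()) -> None:
    """CSV ``id_a,id_b,rmsd,eds,ewcs,crs,nds`` (floats to 6 decimals)."""
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(["id_a", "id_b", "rmsd", "eds", "ewcs", "crs", "nds"])
        for r in results:
            rmsd = "" if r.rmsd is None else f"{r.rmsd:.6f}"
            writer.writerow([r.id_a, r.id_b, rmsd, f"{r.eds:.6f}",
                             f"{r.ewcs:.6f}", f"{r.crs:.6f}", f"{r.nds:.6f}"])


def read_pairwise_csv(path: str | os.PathLike) -> list[ScatterPoint]:
    """Read scatter points back from a pairwise comparison CSV."""
    points = []
    with open(path) as fh:
        rows = (line for line in fh if not line.startswith("#"))
        reader = csv.DictReader(rows)
        required = {"id_a", "id_b", "rmsd", "nds"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for lineno, row in enumerate(reader, 2):
            try:
                points.append(ScatterPoint(id_a=row["id_a"], id_b=row["id_b"],
                                           rmsd=float(row["rmsd"]),
                                           nds=float(row["nds"])))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: row {lineno}: {exc}") from exc
    return points
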