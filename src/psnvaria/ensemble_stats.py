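"""Edge-weight variance across a conformer ensemble.

For every residue pair (union edge set; an edge absent in a conformer
contributes weight 0) the population variance of its edge weight over
the N conformers is computed:

    EV_ij = (1/N) * sum_n (I_n - mu_ij)^2

Highly variable edges are those whose variance exceeds three times the
standard deviation of all edge variances; in descending variance order
the first five are flagged red, the next ten yellow and any remaining
candidates blue.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Sequence

import numpy as np

from .psn_core import PSNGraph

__all__ = ["EnsembleProfile", "edge_variance", "rank_variable_edges",
           "export_edge_attributes"]

HIGHLIGHT_SD_FACTOR = 3.0
N_RED = 5
N_YELLOW = 10


@dataclasses.dataclass
class EnsembleProfile:
    """Per-edge mean and variance over an ensemble, plus highlight classes."""

    labels: tuple[tuple[int, str, str], ...]
    edge_mean: np.ndarray  # n x n symmetric
    edge_variance: np.ndarray  # n x n symmetric, >= 0
    n_conformers: int
    highlight: dict[tuple[int, int], str] = dataclasses.field(default_factory=dict)

    def upper_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        return np.triu_indices(len(self.labels), k=1)


def edge_variance(psns: Sequence[PSNGraph]) -> EnsembleProfile:
    """Population (1/N) mean and variance of every edge weight."""
    if len(psns) < 2:
        raise ValueError("need at least 2 conformers")
    first = psns[0]
    for g in psns[1:]:
        if not g.same_labels(first):
            raise ValueError("all PSNs must share residue labels")
    stack = np.stack([g.weights for g in psns])
    # per-edge sort before accumulation: makes the profile exactly
    # invariant to conformer order and pins constant edges at variance 0
    stack = np.sort(stack, axis=0)
    mean = stack.mean(axis=0)
    var = ((stack - mean) ** 2).mean(axis=0)
    constant = stack[-1] == stack[0]
    var[constant] = 0.0
    mean[constant] = stack[0][constant]
    return EnsembleProfile(labels=first.labels, edge_mean=mean, edge_variance=var,
                           n_conformers=len(psns))


def rank_variable_edges(p: EnsembleProfile) -> list[tuple[int, int, float, str, int]]:
    """Flag and rank the highly variable edges of a profile.

    Candidates are edges with variance strictly above three standard
    deviations of all edge variances; sorted by descending variance
    (ties by residue indices), ranks 1-5 are red, 6-15 yellow and the
    remaining candidates blue.  Mutates ``p.highlight`` and returns the
    ordered candidate report ``(i, j, variance, color, rank)``.
    """
    iu, ju = p.upper_pairs()
    if iu.size == 0:
        raise ValueError("profile has no edges")
    variances = p.edge_variance[iu, ju]
    threshold = HIGHLIGHT_SD_FACTOR * float(np.std(variances))
    p.highlight = {}
    candidates = [(int(i), int(j), float(v))
                  for i, j, v in zip(iu, ju, variances) if v > threshold]
    candidates.sort(key=lambda t: (-t[2], t[0], t[1]))
    report = []
    for rank, (i, j, v) in enumerate(candidates, 1):
        color = "red" if rank <= N_RED else "yellow" if rank <= N_RED + N_YELLOW else "blue"
        p.highlight[(i, j)] = color
        report.append((i, j, v, color, rank))
    return report


def export_edge_attributes(p: EnsembleProfile, path: str | os.PathLike,
                           highlighted_only: bool = False) -> int:
    """Write a molecular-viewer attribute table for the profile.

    Columns: ``resnumA resnumB mean variance color`` for every edge with
    nonzero ensemble mean (or only the highlighted ones when
    ``highlighted_only``).  Returns the number of rows written.
    """
    iu, ju = p.upper_pairs()
    rows = 0
    with open(path, "w") as fh:
        fh.write("# resnumA resnumB mean variance color\n")
        for i, j in zip(iu, ju):
            if p.edge_mean[i, j] == 0.0 and p.edge_variance[i, j] == 0.0:
                continue
            color = p.highlight.get((int(i), int(j)), "none")
            if highlighted_only and color == "none":
                continue
            fh.write(f"{p.labels[i][1]} {p.labels[j][1]} "
                     f"{p.edge_mean[i, j]:.6f} {p.edge_variance[i, j]:.6f} {color}\n")
            rows += 1
    return rows


def read_edge_attributes(path: str | os.PathLike) -> list[tuple[str, str, float, float, str]]:
    """Parse an attribute table written by :func:`export_edge_attributes`."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b, mean, var, color = line.split()
            out.append((a, b, float(mean), float(var), color))
    return out
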