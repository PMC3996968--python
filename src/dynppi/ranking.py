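"""Reconstruction-error profiles, RSD scoring and critical-protein ranking.

Protein i's error at timepoint t is the root-mean-square error between
its row of the original network and its row of the reconstruction,

    Er_i(t) = sqrt( (1/N) * sum_j (A_ij^(t) - A_ij^(R,t))^2 ),

giving an N x T profile. Criticality is the relative standard deviation
RSD = sigma / mu of each profile row: proteins the shared model explains
equally well (or equally badly) at every timepoint score low, proteins
whose local structure the model can only explain at some timepoints score
high. All-zero profiles get RSD 0 by convention — zero error everywhere
is a maximally stable, non-critical protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from dynppi.dynamic_networks import NetworkSeries


@dataclass
class CriticalityReport:
    """Per-protein error profiles, RSD scores and the resulting ranking."""

    protein_ids: list[str]
    er: np.ndarray  # N x T
    rsd: np.ndarray  # N
    ranking: list[str]  # all proteins, most critical first
    top_k: list[str]
    timepoint_labels: list[str]

    def __post_init__(self) -> None:
        if self.er.shape[0] != len(self.protein_ids):
            raise ValueError("er row count does not match protein_ids")
        if sorted(self.ranking) != sorted(self.protein_ids):
            raise ValueError("ranking must be a permutation of protein_ids")
        if (self.er < 0).any() or (self.rsd < 0).any():
            raise ValueError("errors and RSD must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        order = {p: r for r, p in enumerate(self.ranking, start=1)}
        mean_er = self.er.mean(axis=1)
        df = pd.DataFrame(
            {
                "protein": self.protein_ids,
                "rsd": self.rsd,
                "mean_er": mean_er,
                "rank": [order[p] for p in self.protein_ids],
            }
        )
        for t, label in enumerate(self.timepoint_labels):
            df[f"er_{label}"] = self.er[:, t]
        return df.sort_values("rank").reset_index(drop=True)


def rmse_profile(
    original: NetworkSeries, reconstructed: NetworkSeries
) -> np.ndarray:
    """N x T matrix of per-protein, per-timepoint row RMSEs."""
    if original.n_proteins != reconstructed.n_proteins:
        raise ValueError("series sizes differ")
    if original.n_timepoints != reconstructed.n_timepoints:
        raise ValueError("series lengths differ")
    er = np.empty((original.n_proteins, original.n_timepoints))
    for t, (a, r) in enumerate(zip(original.matrices, reconstructed.matrices)):
        er[:, t] = np.sqrt(np.mean((a - r) ** 2, axis=1))
    return er


def rsd(er_row: np.ndarray, ddof: int = 1) -> float:
    """Relative standard deviation sigma/mu of one error profile.

    Uses the sample (ddof=1) standard deviation by default; a zero-mean
    (hence all-zero, errors being non-negative) row returns 0.
    """
    er_row = np.asarray(er_row, dtype=float)
    if er_row.size < 2:
        raise ValueError("need at least 2 timepoints for RSD")
    if (er_row < 0).any():
        raise ValueError("error values must be non-negative")
    mu = er_row.mean()
    if mu == 0:
        return 0.0
    return float(er_row.std(ddof=ddof) / mu)


def rank_critical(
    protein_ids: Sequence[str],
    er: np.ndarray,
    k: int = 150,
    ddof: int = 1,
    timepoint_labels: Sequence[str] | None = None,
) -> CriticalityReport:
    """Rank proteins by descending RSD of their error profiles.

    Ties break by descending mean error, then lexical id, so the ranking
    is fully deterministic. ``top_k`` holds the first min(k, N) proteins.
    """
    protein_ids = list(protein_ids)
    er = np.asarray(er, dtype=float)
    if er.ndim != 2 or er.shape[0] != len(protein_ids):
        raise ValueError("er must be N x T with one row per protein")
    scores = np.array([rsd(row, ddof=ddof) for row in er])
    mean_er = er.mean(axis=1)
    order = sorted(
        range(len(protein_ids)),
        key=lambda i: (-scores[i], -mean_er[i], protein_ids[i]),
    )
    ranking = [protein_ids[i] for i in order]
    labels = (
        list(timepoint_labels)
        if timepoint_labels is not None
        else [f"T{t + 1}" for t in range(er.shape[1])]
    )
    return CriticalityReport(
        protein_ids=protein_ids,
        er=er,
        rsd=scores,
        ranking=ranking,
        top_k=ranking[: min(k, len(ranking))],
        timepoint_labels=labels,
    )


def write_report(path, report: CriticalityReport) -> None:
    """Write the report as TSV (protein, rsd, mean_er, rank, Er columns)."""
    report.to_frame().to_csv(Path(path), sep="\t", index=False)
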