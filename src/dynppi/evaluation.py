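"""Evaluation metrics and shallow reconstruction baselines.

Complex-overlap scoring follows the neighborhood-affinity convention: a
predicted cluster P matches a reference complex R when

    OL(P, R) = |P ∩ R|^2 / (|P| * |R|)

exceeds a threshold (0.2 by default). A ``literal`` form without the
squared numerator is kept as an option; note that under it two identical
size-10 sets score only 0.1 and can never match at 0.2, which is why the
squared form is the default. Precision over a cluster set is
TP / (TP + FP) with TP the clusters matching at least one complex.

Two baselines reconstruct a network series without any deep structure:
``avg_baseline`` repeats the element-wise mean matrix (the least-squares
optimal *time-constant* reconstruction), and ``jnmf_baseline`` is joint
non-negative matrix factorization — one shared non-negative basis W with
per-source coefficients H_t, fitted by multiplicative updates minimizing
sum_t ||A_t - W H_t||_F^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from dynppi.dynamic_networks import NetworkSeries
from dynppi.io_formats import ComplexCatalog

OL_FORMS = ("squared", "literal")


@dataclass
class ClusterSet:
    """Predicted protein clusters plus a provenance label."""

    clusters: list[set[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.clusters:
            raise ValueError("cluster set is empty")
        for c in self.clusters:
            if not c:
                raise ValueError("empty cluster")


@dataclass
class MatchResult:
    """Per-cluster best matches and the resulting precision."""

    best_scores: list[float]
    best_matches: list[Optional[str]]
    tp: int
    fp: int
    prec: float

    def __post_init__(self) -> None:
        if self.tp + self.fp != len(self.best_scores):
            raise ValueError("tp + fp must equal the number of clusters")
        if not 0.0 <= self.prec <= 1.0:
            raise ValueError("precision out of [0, 1]")


def overlap_score(p: set, r: set, form: str = "squared") -> float:
    """Overlap between a predicted cluster and a reference complex."""
    if not p or not r:
        raise ValueError("sets must be non-empty")
    if form not in OL_FORMS:
        raise ValueError(f"form must be one of {OL_FORMS}")
    inter = len(set(p) & set(r))
    if form == "squared":
        return inter**2 / (len(p) * len(r))
    return inter / (len(p) * len(r))


def precision(
    predicted: ClusterSet,
    reference: ComplexCatalog,
    threshold: float = 0.2,
    form: str = "squared",
) -> MatchResult:
    """Match every predicted cluster to its best reference complex.

    A cluster is a true positive when its best overlap score exceeds the
    threshold (strictly), a false positive otherwise.
    """
    best_scores: list[float] = []
    best_matches: list[Optional[str]] = []
    for cluster in predicted.clusters:
        best, who = 0.0, None
        for name, members in reference.complexes:
            score = overlap_score(cluster, members, form=form)
            if score > best:
                best, who = score, name
        best_scores.append(best)
        best_matches.append(who if best > threshold else None)
    tp = sum(1 for m in best_matches if m is not None)
    fp = len(best_matches) - tp
    return MatchResult(best_scores, best_matches, tp, fp, tp / (tp + fp))


def gold_list_precision(
    top_k: Sequence[str], gold: Sequence[str]
) -> tuple[int, float]:
    """Matched count and precision of a ranked list against a gold list."""
    if not top_k:
        raise ValueError("top_k is empty")
    matched = len(set(top_k) & set(gold))
    return matched, matched / len(top_k)


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------


def avg_baseline(series: NetworkSeries) -> NetworkSeries:
    """Reconstruct every timepoint as the element-wise mean matrix.

    This is the exact minimizer of summed squared error among
    reconstructions that are constant in time.
    """
    mean = series.stack().mean(axis=0)
    return NetworkSeries(
        list(series.protein_ids),
        [mean.copy() for _ in series.matrices],
        list(series.timepoint_labels),
    )


def jnmf_baseline(
    series: NetworkSeries,
    rank: Optional[int] = None,
    iterations: int = 200,
    seed: int = 0,
) -> tuple[NetworkSeries, list[float]]:
    """Joint NMF reconstruction: shared basis, per-source coefficients.

    Minimizes sum_t ||A_t - W H_t||_F^2 over W >= 0 (N x rank) and
    H_t >= 0 (rank x N) by multiplicative updates; the objective is
    non-increasing per iteration. Default rank is min(500, N - 1).
    Returns the reconstructions W H_t and the objective history.
    """
    mats = series.stack()
    if mats.min() < 0:
        raise ValueError("joint NMF requires non-negative inputs")
    n = series.n_proteins
    if rank is None:
        rank = min(500, max(1, n - 1))
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(mats.mean(), np.finfo(float).tiny) / rank)
    w = rng.random((n, rank)) * scale
    hs = rng.random((len(series.matrices), rank, n)) * scale
    eps = 1e-12

    objective: list[float] = []
    for _ in range(iterations):
        # per-source coefficient update
        wtw = w.T @ w
        for t, a in enumerate(mats):
            hs[t] *= (w.T @ a) / (wtw @ hs[t] + eps)
        # shared basis update
        num = np.zeros_like(w)
        den = np.zeros((rank, rank))
        for t, a in enumerate(mats):
            num += a @ hs[t].T
            den += hs[t] @ hs[t].T
        w *= num / (w @ den + eps)
        objective.append(
            float(sum(np.sum((a - w @ hs[t]) ** 2) for t, a in enumerate(mats)))
        )

    recon = NetworkSeries(
        list(series.protein_ids),
        [w @ hs[t] for t in range(len(series.matrices))],
        list(series.timepoint_labels),
    )
    return recon, objective
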