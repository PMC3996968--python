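"""Construction of per-timepoint active co-regulation networks.

A protein is *active* at a timepoint when its expression meets a
gene-specific activity threshold (AcScore) derived from the mean and
standard deviation of its expression over the whole course. The dynamic
network at time t is the element-wise product of three masks over one
shared protein index:

    A_t = CoE_t . Act_t . Ppi

where Act_t = delta_t delta_t^T is the outer product of the binary
activity vector, CoE_t holds Pearson co-expression over a sliding
(circular) time window mapped affinely to [0, 1], and Ppi is the static
interactome adjacency. Downstream models consume a higher-order power of
A_t (default the square, diagonal zeroed, rescaled to [0, 1]) so that a
protein's row reflects its two-step neighborhood, mimicking short random
walks on the instant network.

Two AcScore forms are provided. ``range_consistent`` (default) is the
three-sigma-style threshold

    AcScore(p) = mu(p) + alpha * sigma(p)^3 / (1 + sigma(p)^2)

whose tunable weight alpha keeps the score within
(mu, mu + alpha*sigma^3/(1+sigma^2)). ``eq1_literal`` is the alternative
weighted-threshold form AcScore = thr1*F + thr2*(1-F) with thr1 = mu,
thr2 = mu*sigma and F = 1/(1+sigma); it has no alpha. Both reduce to mu
when sigma = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from dynppi.io_formats import EdgeList, ExpressionMatrix

logger = logging.getLogger(__name__)

ACTIVITY_FORMS = ("range_consistent", "eq1_literal")


@dataclass
class ActivityModel:
    """Per-protein activity thresholds fitted on a whole expression course."""

    gene_ids: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    f: np.ndarray
    thr1: np.ndarray
    thr2: np.ndarray
    alpha: float
    ac_score: np.ndarray
    form: str


@dataclass
class NetworkSeries:
    """Ordered list of T square matrices over one shared protein index."""

    protein_ids: list[str]
    matrices: list[np.ndarray]
    timepoint_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.protein_ids)
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]
        for t, m in enumerate(self.matrices):
            if m.shape != (n, n):
                raise ValueError(f"matrix {t} has shape {m.shape}, expected ({n},{n})")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"matrix {t} contains non-finite entries")
        if not self.timepoint_labels:
            self.timepoint_labels = [f"T{t + 1}" for t in range(len(self.matrices))]
        if len(self.timepoint_labels) != len(self.matrices):
            raise ValueError("timepoint_labels length does not match matrices")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_timepoints(self) -> int:
        return len(self.matrices)

    def stack(self) -> np.ndarray:
        """All matrices as one T x N x N array."""
        return np.stack(self.matrices)


def validate_series(
    series: NetworkSeries,
    symmetric: bool = True,
    unit_interval: bool = False,
    atol: float = 1e-12,
) -> None:
    """Raise if the series violates construction invariants."""
    for t, m in enumerate(series.matrices):
        if symmetric and not np.allclose(m, m.T, atol=atol):
            raise ValueError(f"matrix {t} is not symmetric")
        if unit_interval and (m.min() < -atol or m.max() > 1 + atol):
            raise ValueError(f"matrix {t} has entries outside [0, 1]")


# ---------------------------------------------------------------------------
# Activity
# ---------------------------------------------------------------------------


def compute_activity_scores(
    expr: ExpressionMatrix,
    alpha: float = 1.5,
    form: str = "range_consistent",
    reference: Optional[ExpressionMatrix] = None,
) -> ActivityModel:
    """Fit per-gene activity thresholds from pooled expression values.

    When ``reference`` is given (a second expression series over an
    overlapping gene set), mu and sigma are computed over the pooled
    samples of both series for the shared genes, damping course-specific
    bias in the estimates. Genes absent from the reference use their own
    samples only.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if form not in ACTIVITY_FORMS:
        raise ValueError(f"form must be one of {ACTIVITY_FORMS}")

    pooled = [row for row in expr.pooled()]
    if reference is not None:
        ref_index = {g: i for i, g in enumerate(reference.gene_ids)}
        ref_pooled = reference.pooled()
        shared = 0
        for i, g in enumerate(expr.gene_ids):
            j = ref_index.get(g)
            if j is not None:
                pooled[i] = np.concatenate([pooled[i], ref_pooled[j]])
                shared += 1
        if shared == 0:
            raise ValueError("reference series shares no genes with expression")

    mu = np.array([row.mean() for row in pooled])
    sigma = np.array(
        [row.std(ddof=1) if row.size > 1 else 0.0 for row in pooled]
    )
    f = 1.0 / (1.0 + sigma)
    thr1 = mu
    thr2 = mu * sigma
    if form == "eq1_literal":
        ac_score = thr1 * f + thr2 * (1.0 - f)
    else:
        ac_score = mu + alpha * sigma**3 / (1.0 + sigma**2)
    return ActivityModel(
        gene_ids=list(expr.gene_ids),
        mu=mu,
        sigma=sigma,
        f=f,
        thr1=thr1,
        thr2=thr2,
        alpha=alpha,
        ac_score=ac_score,
        form=form,
    )


def binarize_activity(
    expr: ExpressionMatrix, model: ActivityModel, t: int
) -> np.ndarray:
    """Binary activity vector at timepoint t.

    delta_t(p) = 1 iff g_t(p) >= AcScore(p), with g_t(p) the replicate
    mean of p's expression at t; the threshold is inclusive.
    """
    if not 0 <= t < expr.n_timepoints:
        raise IndexError(f"timepoint {t} out of range")
    if model.gene_ids != expr.gene_ids:
        raise ValueError("activity model fitted on a different gene set")
    g_t = expr.values[:, t, :].mean(axis=1)
    return (g_t >= model.ac_score).astype(float)


def activity_network(delta: np.ndarray) -> np.ndarray:
    """Rank-<=1 co-activity matrix delta delta^T (1 iff both active)."""
    delta = np.asarray(delta, dtype=float)
    if not np.isin(delta, (0.0, 1.0)).all():
        raise ValueError("activity vector must be binary")
    return np.outer(delta, delta)


# ---------------------------------------------------------------------------
# Co-expression
# ---------------------------------------------------------------------------


def windowed_coexpression(
    expr: ExpressionMatrix, t: int, half_width: int = 1
) -> np.ndarray:
    """Pairwise co-expression at timepoint t over a circular window.

    Pools the replicates of timepoints {t-half_width .. t+half_width}
    (circular wrap, so the first timepoint's predecessor is the last) and
    computes Pearson r over those samples, mapped to [0, 1] by
    CoE = (r + 1) / 2. Pairs where either profile is constant in the
    window take r = 0, i.e. CoE = 0.5.
    """
    if not 0 <= t < expr.n_timepoints:
        raise IndexError(f"timepoint {t} out of range")
    if expr.n_timepoints < 2:
        raise ValueError("need at least 2 timepoints for co-expression")
    idx = [(t + o) % expr.n_timepoints for o in range(-half_width, half_width + 1)]
    window = expr.values[:, idx, :].reshape(expr.n_genes, -1)
    if window.shape[1] < 3:
        raise ValueError("co-expression window has fewer than 3 samples")

    centered = window - window.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    nonconst = norms > 0
    unit = np.zeros_like(centered)
    unit[nonconst] = centered[nonconst] / norms[nonconst, None]
    r = np.clip(unit @ unit.T, -1.0, 1.0)
    # constant profiles have all-zero unit rows, hence r = 0 against anything
    diag = np.where(nonconst, 1.0, 0.0)
    np.fill_diagonal(r, diag)
    return (r + 1.0) / 2.0


# ---------------------------------------------------------------------------
# Combination and higher order
# ---------------------------------------------------------------------------


def combine_networks(
    coe: np.ndarray, act: np.ndarray, ppi: np.ndarray
) -> np.ndarray:
    """Element-wise product A_t = CoE_t . Act_t . Ppi."""
    coe, act, ppi = (np.asarray(m, dtype=float) for m in (coe, act, ppi))
    if not (coe.shape == act.shape == ppi.shape):
        raise ValueError("matrix shapes differ")
    if not np.isin(ppi, (0.0, 1.0)).all():
        raise ValueError("ppi adjacency must be binary")
    if not np.array_equal(ppi, ppi.T):
        raise ValueError("ppi adjacency must be symmetric")
    if np.diagonal(ppi).any():
        raise ValueError("ppi adjacency must have zero diagonal")
    return coe * act * ppi


def higher_order(
    a: np.ndarray, order: int = 2, rescale: str = "max"
) -> np.ndarray:
    """Matrix power of a network, diagonal zeroed, optionally rescaled.

    ``rescale='max'`` divides by the maximum entry so results stay in
    [0, 1] and can feed Bernoulli visible units; an all-zero matrix is
    returned unchanged.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if rescale not in ("max", "none"):
        raise ValueError(f"unknown rescale {rescale!r}")
    a = np.asarray(a, dtype=float)
    if a.min() < 0:
        raise ValueError("network must be non-negative")
    if not np.allclose(a, a.T):
        raise ValueError("network must be symmetric")
    m = np.linalg.matrix_power(a, order)
    np.fill_diagonal(m, 0.0)
    if rescale == "max":
        mx = m.max()
        if mx > 0:
            m = m / mx
    return m


# ---------------------------------------------------------------------------
# Full construction
# ---------------------------------------------------------------------------


def build_series(
    expr: ExpressionMatrix,
    edges: EdgeList,
    alpha: float = 1.5,
    form: str = "range_consistent",
    order: int = 2,
    rescale: str = "series_max",
    half_width: int = 1,
    reference: Optional[ExpressionMatrix] = None,
) -> NetworkSeries:
    """Build the T higher-order dynamic networks from expression + PPIN.

    The protein index is the intersection of the expression gene set and
    the interactome's proteins (expression order preserved). Per-timepoint
    active-protein and edge counts are logged at INFO level.

    ``rescale`` controls how the higher-order matrices are brought into
    [0, 1]: ``series_max`` (default) divides every timepoint by one
    series-wide maximum, so the same structure keeps the same value at
    every timepoint — reconstruction errors are then comparable across
    time; ``matrix_max`` rescales each timepoint by its own maximum;
    ``none`` leaves raw matrix powers.
    """
    if rescale not in ("series_max", "matrix_max", "none"):
        raise ValueError(f"unknown rescale {rescale!r}")
    ppi_proteins = set(edges.proteins())
    shared = [g for g in expr.gene_ids if g in ppi_proteins]
    if not shared:
        raise ValueError("empty protein intersection between expression and PPIN")
    sub = expr.subset(shared)
    ppi = edges.to_adjacency(shared)
    model = compute_activity_scores(sub, alpha=alpha, form=form, reference=reference)

    matrices = []
    for t in range(sub.n_timepoints):
        delta = binarize_activity(sub, model, t)
        act = activity_network(delta)
        coe = windowed_coexpression(sub, t, half_width=half_width)
        a_t = combine_networks(coe, act, ppi)
        n_active = int(delta.sum())
        n_edges = int(np.count_nonzero(np.triu(a_t, k=1)))
        logger.info(
            "timepoint %s: %d active proteins, %d interactions",
            sub.timepoint_labels[t],
            n_active,
            n_edges,
        )
        matrices.append(
            higher_order(
                a_t, order=order, rescale="max" if rescale == "matrix_max" else "none"
            )
        )
    if rescale == "series_max":
        top = max(m.max() for m in matrices)
        if top > 0:
            matrices = [m / top for m in matrices]
    series = NetworkSeries(shared, matrices, list(sub.timepoint_labels))
    validate_series(series, symmetric=True, unit_interval=(rescale != "none"))
    return series


def series_stats(
    expr: ExpressionMatrix,
    edges: EdgeList,
    alpha: float = 1.5,
    form: str = "range_consistent",
    half_width: int = 1,
    reference: Optional[ExpressionMatrix] = None,
) -> list[dict]:
    """Per-timepoint active-protein and interaction counts of A_t."""
    ppi_proteins = set(edges.proteins())
    shared = [g for g in expr.gene_ids if g in ppi_proteins]
    if not shared:
        raise ValueError("empty protein intersection between expression and PPIN")
    sub = expr.subset(shared)
    ppi = edges.to_adjacency(shared)
    model = compute_activity_scores(sub, alpha=alpha, form=form, reference=reference)
    out = []
    for t in range(sub.n_timepoints):
        delta = binarize_activity(sub, model, t)
        a_t = combine_networks(
            windowed_coexpression(sub, t, half_width=half_width),
            activity_network(delta),
            ppi,
        )
        out.append(
            {
                "timepoint": sub.timepoint_labels[t],
                "active_proteins": int(delta.sum()),
                "interactions": int(np.count_nonzero(np.triu(a_t, k=1))),
            }
        )
    return out
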