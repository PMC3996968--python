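"""Readers and writers for the pipeline's external file formats.

Formats are deliberately plain: tab-separated tables with ``#`` comment
lines, GEO-series-matrix-like wide tables (``!`` metadata lines), 2+ column
edge lists, one-complex-per-line catalogs and one-id-per-line gene lists.
Gene/protein identifiers are opaque strings; no alias mapping is attempted.

The network-series container is a directory holding a versioned JSON
metadata file plus one dense TSV matrix per timepoint, written with full
float precision so round trips are bit-faithful. Model checkpoints use
NumPy ``.npz`` archives.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

SERIES_FORMAT_VERSION = 1
MODEL_FORMAT_VERSION = 1


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene expression time course: genes x timepoints x replicates.

    Replicates are the same timepoint observed in successive cycles of a
    periodic experiment (e.g. a metabolic-cycle series with 12 timepoints
    per cycle over 3 cycles has 12 timepoints and 3 replicates).
    """

    gene_ids: list[str]
    values: np.ndarray
    timepoint_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be genes x timepoints x replicates")
        n_genes, n_t, n_rep = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match values")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene identifiers")
        if n_rep < 1:
            raise ValueError("need at least one replicate")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if not self.timepoint_labels:
            self.timepoint_labels = [f"T{t + 1}" for t in range(n_t)]
        if len(self.timepoint_labels) != n_t:
            raise ValueError("timepoint_labels length does not match values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def replicate_mean(self) -> np.ndarray:
        """Per-gene, per-timepoint mean over replicates (genes x T)."""
        return self.values.mean(axis=2)

    def pooled(self) -> np.ndarray:
        """All samples of each gene as one row (genes x T*replicates)."""
        return self.values.reshape(self.n_genes, -1)

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            list(gene_ids), self.values[rows], list(self.timepoint_labels)
        )


@dataclass
class EdgeList:
    """Undirected interaction pairs; no self-loops, no duplicates."""

    pairs: set[tuple[str, str]]

    def __post_init__(self) -> None:
        canon = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-loop {a!r} in EdgeList")
            canon.add((a, b) if a <= b else (b, a))
        self.pairs = canon

    def __len__(self) -> int:
        return len(self.pairs)

    def proteins(self) -> list[str]:
        out: set[str] = set()
        for a, b in self.pairs:
            out.add(a)
            out.add(b)
        return sorted(out)

    def to_adjacency(self, protein_ids: Sequence[str]) -> np.ndarray:
        """Binary symmetric adjacency over the given ordering.

        Edges whose endpoints are not both in ``protein_ids`` are dropped.
        """
        index = {p: i for i, p in enumerate(protein_ids)}
        n = len(protein_ids)
        adj = np.zeros((n, n))
        for a, b in self.pairs:
            i, j = index.get(a), index.get(b)
            if i is None or j is None:
                continue
            adj[i, j] = adj[j, i] = 1.0
        return adj


@dataclass
class ComplexCatalog:
    """Named reference protein complexes (e.g. a curated catalog)."""

    complexes: list[tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for name, members in self.complexes:
            if not members:
                raise ValueError(f"empty complex {name!r}")

    def __len__(self) -> int:
        return len(self.complexes)


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------


def _data_lines(path: Path, skip_prefixes: tuple[str, ...] = ("#",)):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(skip_prefixes):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def read_expression(
    path,
    layout: str = "wide_tsv",
    cycles: int = 1,
    column_order: str = "cycle_major",
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples table and fold cycles into replicates.

    Parameters
    ----------
    layout
        ``wide_tsv``: gene id in column 0, one sample per further column,
        ``#`` comments allowed. ``series_matrix``: same table but with GEO
        series-matrix dressing — ``!`` metadata lines are skipped and the
        first remaining row is treated as a header and dropped.
    cycles
        Number of replicate cycles folded into the replicate axis. The
        sample-column count must be divisible by ``cycles``.
    column_order
        ``cycle_major`` (cycle 1 timepoints 1..T, then cycle 2, ...) or
        ``timepoint_major`` (all cycles of timepoint 1 first).
    impute_missing
        Replace empty/NA fields with the row mean instead of failing.
    """
    path = Path(path)
    if layout not in ("wide_tsv", "series_matrix"):
        raise ValueError(f"unknown layout {layout!r}")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if column_order not in ("cycle_major", "timepoint_major"):
        raise ValueError(f"unknown column_order {column_order!r}")

    skip = ("#", "!") if layout == "series_matrix" else ("#",)
    rows: list[tuple[str, list[float]]] = []
    n_fields = None
    header_skipped = layout != "series_matrix"
    missing_tokens = ("", "NA", "NaN", "null")
    for lineno, line in _data_lines(path, skip):
        fields = line.split("\t")
        if not header_skipped:
            header_skipped = True
            continue
        if n_fields is None:
            n_fields = len(fields)
            if n_fields < 2:
                raise ParseError(f"{path}:{lineno}: expected id + samples")
        elif len(fields) != n_fields:
            raise ParseError(
                f"{path}:{lineno}: expected {n_fields} fields, got {len(fields)}"
            )
        vals: list[float] = []
        for f in fields[1:]:
            if f.strip() in missing_tokens:
                if not impute_missing:
                    raise ParseError(f"{path}:{lineno}: missing value")
                vals.append(np.nan)
            else:
                try:
                    vals.append(float(f))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad number {f!r}") from exc
        rows.append((fields[0], vals))

    if not rows:
        raise ParseError(f"{path}: no data rows")
    gene_ids = [g for g, _ in rows]
    if len(set(gene_ids)) != len(gene_ids):
        dup = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ParseError(f"{path}: duplicate gene id(s): {dup[:5]}")

    data = np.array([v for _, v in rows], dtype=float)
    if impute_missing and np.isnan(data).any():
        row_means = np.nanmean(data, axis=1, keepdims=True)
        data = np.where(np.isnan(data), row_means, data)
    n_samples = data.shape[1]
    if n_samples % cycles:
        raise ParseError(
            f"{path}: {n_samples} sample columns not divisible by cycles={cycles}"
        )
    n_t = n_samples // cycles
    if column_order == "cycle_major":
        values = data.reshape(len(rows), cycles, n_t).transpose(0, 2, 1)
    else:
        values = data.reshape(len(rows), n_t, cycles)
    return ExpressionMatrix(gene_ids, values)


def write_expression(
    path, expr: ExpressionMatrix, column_order: str = "cycle_major"
) -> None:
    """Write an expression matrix back to the wide TSV layout."""
    if column_order == "cycle_major":
        flat = expr.values.transpose(0, 2, 1).reshape(expr.n_genes, -1)
    elif column_order == "timepoint_major":
        flat = expr.values.reshape(expr.n_genes, -1)
    else:
        raise ValueError(f"unknown column_order {column_order!r}")
    with open(path, "w") as fh:
        for gid, row in zip(expr.gene_ids, flat):
            fh.write(gid + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Edge lists, complexes, gene lists, clusters
# ---------------------------------------------------------------------------


def read_edge_list(path, columns: tuple[int, int] = (0, 1)) -> EdgeList:
    """Read an interaction edge list (2+ tab-separated columns).

    Self-loops are dropped (count logged) and duplicate pairs collapsed.
    An empty file yields an empty EdgeList with a warning.
    """
    path = Path(path)
    ca, cb = columns
    need = max(ca, cb) + 1
    pairs: set[tuple[str, str]] = set()
    self_loops = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < need:
            raise ParseError(
                f"{path}:{lineno}: expected >= {need} fields, got {len(fields)}"
            )
        a, b = fields[ca].strip(), fields[cb].strip()
        if a == b:
            self_loops += 1
            continue
        pairs.add((a, b) if a <= b else (b, a))
    if self_loops:
        logger.info("dropped %d self-loop(s) from %s", self_loops, path)
    if not pairs:
        logger.warning("edge list %s is empty", path)
    return EdgeList(pairs)


def write_edge_list(path, edges: EdgeList) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(edges.pairs):
            fh.write(f"{a}\t{b}\n")


def read_complex_catalog(path) -> ComplexCatalog:
    """One complex per line: name, then tab-separated member ids."""
    path = Path(path)
    complexes: list[tuple[str, frozenset[str]]] = []
    for lineno, line in _data_lines(path):
        fields = [f for f in line.split("\t") if f.strip()]
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: empty complex")
        complexes.append((fields[0], frozenset(fields[1:])))
    return ComplexCatalog(complexes)


def read_gene_list(path) -> list[str]:
    """One identifier per line; order preserved, duplicates collapsed."""
    seen: dict[str, None] = {}
    for _, line in _data_lines(Path(path)):
        seen.setdefault(line.split("\t")[0].strip(), None)
    return list(seen)


def read_cluster_file(path) -> list[set[str]]:
    """Predicted clusters, one per line, tab-separated member ids."""
    path = Path(path)
    clusters: list[set[str]] = []
    for lineno, line in _data_lines(path):
        members = {f.strip() for f in line.split("\t") if f.strip()}
        if not members:
            raise ParseError(f"{path}:{lineno}: empty cluster")
        clusters.append(members)
    return clusters


# ---------------------------------------------------------------------------
# Network series container
# ---------------------------------------------------------------------------


def write_network_series(path, series) -> None:
    """Write a NetworkSeries to a directory (JSON metadata + TSV matrices)."""
    if not series.matrices:
        raise ValueError("refusing to write an empty network series")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": SERIES_FORMAT_VERSION,
        "protein_ids": list(series.protein_ids),
        "timepoint_labels": list(series.timepoint_labels),
        "n_timepoints": len(series.matrices),
    }
    (path / "series.json").write_text(json.dumps(meta, indent=1))
    for t, mat in enumerate(series.matrices):
        np.savetxt(path / f"matrix_{t:03d}.tsv", mat, fmt="%.17g", delimiter="\t")


def read_network_series(path):
    """Read a NetworkSeries written by :func:`write_network_series`."""
    from dynppi.dynamic_networks import NetworkSeries

    path = Path(path)
    meta_path = path / "series.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"{meta_path} not found")
    meta = json.loads(meta_path.read_text())
    if meta.get("format_version") != SERIES_FORMAT_VERSION:
        raise ValueError(f"unsupported series format {meta.get('format_version')!r}")
    n = len(meta["protein_ids"])
    matrices = []
    for t in range(meta["n_timepoints"]):
        mat = np.loadtxt(path / f"matrix_{t:03d}.tsv", delimiter="\t", ndmin=2)
        if mat.shape != (n, n):
            raise ValueError(f"matrix {t} has shape {mat.shape}, expected ({n},{n})")
        matrices.append(mat)
    return NetworkSeries(meta["protein_ids"], matrices, meta["timepoint_labels"])


# ---------------------------------------------------------------------------
# Model checkpoints
# ---------------------------------------------------------------------------


def save_model(path, model) -> None:
    """Persist an MsiDBNModel (all weights, biases and layer metadata)."""
    arrays: dict[str, np.ndarray] = {}
    for stack in model.stacks:
        for li, layer in enumerate((stack.layer1, stack.layer2), start=1):
            pre = f"stack{stack.t}_l{li}"
            arrays[f"{pre}_w"] = layer.w
            arrays[f"{pre}_b"] = layer.b
            arrays[f"{pre}_d"] = layer.d
    arrays["joint_w"] = model.joint.rbm.w
    arrays["joint_b"] = model.joint.rbm.b
    arrays["joint_d"] = model.joint.rbm.d
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "layer_sizes": list(model.layer_sizes),
        "n_sources": len(model.stacks),
        "protein_ids": list(model.protein_ids),
        "training_log": model.training_log,
    }
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_model(path):
    """Load an MsiDBNModel saved by :func:`save_model`."""
    from dynppi.msidbn import JointLayer, MsiDBNModel, SourceStack
    from dynppi.rbm import RBMParameters

    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["meta_json"]))
        if meta.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        n, h1, h2, j = meta["layer_sizes"]
        stacks = []
        for t in range(meta["n_sources"]):
            layers = []
            for li in (1, 2):
                pre = f"stack{t}_l{li}"
                layers.append(
                    RBMParameters(npz[f"{pre}_w"], npz[f"{pre}_b"], npz[f"{pre}_d"])
                )
            stacks.append(SourceStack(t, layers[0], layers[1]))
        joint = JointLayer(
            RBMParameters(npz["joint_w"], npz["joint_b"], npz["joint_d"]),
            n_sources=meta["n_sources"],
            block_size=h2,
        )
    return MsiDBNModel(
        stacks=stacks,
        joint=joint,
        layer_sizes=tuple(meta["layer_sizes"]),
        protein_ids=meta["protein_ids"],
        training_log=meta["training_log"],
    )
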