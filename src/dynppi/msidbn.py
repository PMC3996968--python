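"""Multi-source integrated deep belief network.

Each of the T timepoint networks is a *source*: protein i's training
vector for source t is row i of the (rescaled, zero-diagonal) higher-order
adjacency at time t. Every source gets its own two-layer stack of RBMs
(v^(t) -> h1^(t) -> h2^(t), weights untied across sources); a single joint
RBM then sits on the concatenation of all h2^(t) activation probabilities
and extracts J shared hidden factors h common to all timepoints:

    P(h2^(t) | h)          = sigmoid(d_t + W3^(t) h)
    P(h | h2^(1..T))       = sigmoid(c + sum_t W3^(t)^T h2^(t))

Training is greedy and layer-wise by contrastive divergence: per-source
layer 1, per-source layer 2 (on layer-1 hidden probabilities), then the
joint layer; lower layers stay frozen while the joint layer trains. The
two-layer stacks are trained with identical seeds across sources, so
identical inputs yield identical stacks and permuting identical sources
leaves the shared encoding unchanged.

Encoding and reconstruction are deterministic mean-field passes
(probabilities propagated through the sigmoids, no sampling), which makes
the downstream reconstruction-error ranking reproducible; sampling the
downward pass can be re-enabled with ``sample=True`` and a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from dynppi.dynamic_networks import NetworkSeries
from dynppi.rbm import (
    RBMParameters,
    TrainConfig,
    prob_h_given_v,
    prob_v_given_h,
    train,
)

logger = logging.getLogger(__name__)


@dataclass
class SourceStack:
    """One source's two RBM layers (v -> h1 -> h2)."""

    t: int
    layer1: RBMParameters
    layer2: RBMParameters

    def __post_init__(self) -> None:
        if self.layer2.n_visible != self.layer1.n_hidden:
            raise ValueError("layer2 visible size must equal layer1 hidden size")


@dataclass
class JointLayer:
    """Shared top RBM over the concatenated per-source h2 layers."""

    rbm: RBMParameters
    n_sources: int
    block_size: int

    def __post_init__(self) -> None:
        if self.rbm.n_visible != self.n_sources * self.block_size:
            raise ValueError("joint visible size must be n_sources * block_size")

    @property
    def n_shared(self) -> int:
        return self.rbm.n_hidden

    @property
    def c(self) -> np.ndarray:
        """Shared-hidden bias c_k."""
        return self.rbm.d

    def w3_block(self, t: int) -> np.ndarray:
        """Weight block W3^(t) (shared-hidden x h2^(t))."""
        s = slice(t * self.block_size, (t + 1) * self.block_size)
        return self.rbm.w[:, s]

    def d_block(self, t: int) -> np.ndarray:
        """Per-source visible bias d_t over h2^(t)."""
        s = slice(t * self.block_size, (t + 1) * self.block_size)
        return self.rbm.b[s]


@dataclass
class MsiDBNModel:
    """T per-source stacks plus the joint top layer."""

    stacks: list[SourceStack]
    joint: JointLayer
    layer_sizes: tuple[int, int, int, int]  # (N, h1, h2, J)
    protein_ids: list[str] = field(default_factory=list)
    training_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, h1, h2, j = self.layer_sizes
        for stack in self.stacks:
            if stack.layer1.w.shape != (h1, n) or stack.layer2.w.shape != (h2, h1):
                raise ValueError("stack layer sizes inconsistent with layer_sizes")
        if self.joint.rbm.w.shape != (j, len(self.stacks) * h2):
            raise ValueError("joint layer sizes inconsistent with layer_sizes")

    @property
    def n_sources(self) -> int:
        return len(self.stacks)


def default_layer_sizes(n: int, joint_size: int = 32) -> tuple[int, int, int]:
    """(h1, h2, J) defaults for N visible units."""
    return min(256, n), min(128, n), joint_size


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def pretrain_stacks(
    series: NetworkSeries,
    sizes: tuple[int, int],
    config: TrainConfig,
) -> tuple[list[SourceStack], dict]:
    """Greedy layer-wise CD pretraining of one 2-layer stack per source.

    Layer 1 trains on the rows of the t-th matrix; layer 2 trains on
    layer 1's hidden activation probabilities. Seeds depend only on the
    layer, not the source, so identical sources give identical stacks.
    """
    n_h1, n_h2 = sizes
    if n_h1 < 1 or n_h2 < 1:
        raise ValueError("layer sizes must be positive")
    n = series.n_proteins
    if n_h1 >= n or n_h2 >= n:
        logger.warning(
            "over-complete hidden layer (h1=%d, h2=%d, N=%d)", n_h1, n_h2, n
        )
    stacks: list[SourceStack] = []
    log: dict = {"layer1_errors": [], "layer2_errors": []}
    cfg1, cfg2 = config.derive(0), config.derive(1)
    for t, mat in enumerate(series.matrices):
        init1 = RBMParameters.initialize(n_h1, n, config.init_scale, cfg1.seed)
        layer1, hist1 = train(init1, mat, cfg1)
        hidden1 = prob_h_given_v(layer1, mat)
        init2 = RBMParameters.initialize(n_h2, n_h1, config.init_scale, cfg2.seed)
        layer2, hist2 = train(init2, hidden1, cfg2)
        stacks.append(SourceStack(t, layer1, layer2))
        log["layer1_errors"].append(hist1)
        log["layer2_errors"].append(hist2)
    return stacks, log


def _h2_concat(stacks: Sequence[SourceStack], series: NetworkSeries) -> np.ndarray:
    """Per-protein concatenation of all sources' h2 activation probabilities."""
    blocks = []
    for stack, mat in zip(stacks, series.matrices):
        h1 = prob_h_given_v(stack.layer1, mat)
        blocks.append(prob_h_given_v(stack.layer2, h1))
    return np.concatenate(blocks, axis=1)


def train_joint(
    stacks: Sequence[SourceStack],
    series: NetworkSeries,
    joint_size: int,
    config: TrainConfig,
) -> tuple[JointLayer, list[float]]:
    """Train the shared top RBM on the concatenated h2 probabilities."""
    if joint_size < 1:
        raise ValueError("joint layer size must be >= 1")
    if len(stacks) != series.n_timepoints:
        raise ValueError("one stack per source required")
    data = _h2_concat(stacks, series)
    cfg = config.derive(2)
    init = RBMParameters.initialize(
        joint_size, data.shape[1], config.init_scale, cfg.seed
    )
    params, hist = train(init, data, cfg)
    block = stacks[0].layer2.n_hidden
    return JointLayer(params, n_sources=len(stacks), block_size=block), hist


def train_full(
    series: NetworkSeries,
    sizes: Optional[tuple[int, int]] = None,
    joint_size: int = 32,
    config: Optional[TrainConfig] = None,
) -> MsiDBNModel:
    """Pretrain all stacks, then the joint layer; assemble the model."""
    config = config or TrainConfig()
    n = series.n_proteins
    if sizes is None:
        h1, h2, _ = default_layer_sizes(n, joint_size)
        sizes = (h1, h2)
    stacks, log = pretrain_stacks(series, sizes, config)
    joint, joint_hist = train_joint(stacks, series, joint_size, config)
    log["joint_errors"] = joint_hist
    return MsiDBNModel(
        stacks=stacks,
        joint=joint,
        layer_sizes=(n, sizes[0], sizes[1], joint_size),
        protein_ids=list(series.protein_ids),
        training_log=log,
    )


# ---------------------------------------------------------------------------
# Encoding and reconstruction
# ---------------------------------------------------------------------------


def _check_compat(model: MsiDBNModel, series: NetworkSeries) -> None:
    if series.n_timepoints != model.n_sources:
        raise ValueError(
            f"series has {series.n_timepoints} sources, model expects "
            f"{model.n_sources}"
        )
    if series.n_proteins != model.layer_sizes[0]:
        raise ValueError(
            f"series has {series.n_proteins} proteins, model expects "
            f"{model.layer_sizes[0]}"
        )


def encode(model: MsiDBNModel, series: NetworkSeries) -> np.ndarray:
    """Deterministic mean-field upward pass to the shared layer (N x J)."""
    _check_compat(model, series)
    return prob_h_given_v(model.joint.rbm, _h2_concat(model.stacks, series))


def reconstruct(
    model: MsiDBNModel,
    series: NetworkSeries,
    sample: bool = False,
    seed: int = 0,
) -> NetworkSeries:
    """Reconstruct every source from the shared encoding.

    Downward pass P(h) -> P(h2^(t)|h) -> P(h1^(t)) -> P(v^(t)); all
    mean-field by default (entries in (0, 1)). With ``sample=True`` the
    h2 layer is Bernoulli-sampled from P(h2^(t)|h) before propagating.
    """
    _check_compat(model, series)
    shared = encode(model, series)
    h2_all = prob_v_given_h(model.joint.rbm, shared)
    rng = np.random.default_rng(seed) if sample else None
    matrices = []
    bs = model.joint.block_size
    for t, stack in enumerate(model.stacks):
        h2 = h2_all[:, t * bs : (t + 1) * bs]
        if rng is not None:
            h2 = (rng.random(h2.shape) < h2).astype(float)
        h1 = prob_v_given_h(stack.layer2, h2)
        v = prob_v_given_h(stack.layer1, h1)
        matrices.append(v)
    return NetworkSeries(
        list(series.protein_ids), matrices, list(series.timepoint_labels)
    )
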