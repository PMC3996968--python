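"""Restricted Boltzmann machine with contrastive-divergence training.

The energy convention here is E(v, h) = h^T W v + d^T h + b^T v with the
joint distribution P(v, h) = exp(E) / Z — i.e. *higher* energy means
higher probability (the negative of the more common convention; kept
because the sigmoid conditionals below then read off E directly):

    P(h_j = 1 | v) = sigmoid(d_j + sum_i W_ji v_i)
    P(v_i = 1 | h) = sigmoid(b_i + sum_j W_ji h_j)

Training maximizes the data log-likelihood by CD-k: the positive phase
uses hidden activation probabilities against the data, the negative phase
runs a k-step alternating Gibbs chain started at the data. Hidden states
are sampled along the chain; the final visible reconstruction is
mean-field (probabilities, not samples), a standard variance-reduction
choice. Visible inputs may be real-valued in [0, 1] and are used directly
as Bernoulli means.

An exact-enumeration likelihood (feasible up to ~20 total units) is
provided so small models can be checked against brute force.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.special import expit, logsumexp


@dataclass
class RBMParameters:
    """One layer's weights (hidden x visible) and bias vectors."""

    w: np.ndarray
    b: np.ndarray  # visible bias
    d: np.ndarray  # hidden bias

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.w.shape != (self.d.size, self.b.size):
            raise ValueError(
                f"weight shape {self.w.shape} inconsistent with biases "
                f"({self.d.size} hidden, {self.b.size} visible)"
            )
        for arr in (self.w, self.b, self.d):
            if not np.all(np.isfinite(arr)):
                raise ValueError("parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.b.size

    @property
    def n_hidden(self) -> int:
        return self.d.size

    def copy(self) -> "RBMParameters":
        return RBMParameters(self.w.copy(), self.b.copy(), self.d.copy())

    @classmethod
    def initialize(
        cls, n_hidden: int, n_visible: int, scale: float = 0.01, seed: int = 0
    ) -> "RBMParameters":
        rng = np.random.default_rng(seed)
        return cls(
            rng.normal(0.0, scale, size=(n_hidden, n_visible)),
            np.zeros(n_visible),
            np.zeros(n_hidden),
        )


@dataclass
class TrainConfig:
    """CD training hyperparameters (all design choices, all overridable)."""

    cd_k: int = 1
    learning_rate: float = 0.05
    epochs: int = 100
    batch_size: int = 16
    seed: int = 0
    init_scale: float = 0.01

    def __post_init__(self) -> None:
        if self.cd_k < 1:
            raise ValueError("cd_k must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def derive(self, offset: int) -> "TrainConfig":
        """Same config with a deterministically shifted seed."""
        return replace(self, seed=(self.seed + offset) % (2**31))


# ---------------------------------------------------------------------------
# Energy and conditionals
# ---------------------------------------------------------------------------


def energy(params: RBMParameters, v: np.ndarray, h: np.ndarray) -> float:
    """E(v, h) = h^T W v + d^T h + b^T v (P is proportional to exp E)."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    return float(h @ params.w @ v + params.d @ h + params.b @ v)


def prob_h_given_v(params: RBMParameters, v: np.ndarray) -> np.ndarray:
    """P(h_j = 1 | v), vectorized over rows when v is 2-D."""
    v = np.asarray(v, dtype=float)
    return expit(v @ params.w.T + params.d)


def prob_v_given_h(params: RBMParameters, h: np.ndarray) -> np.ndarray:
    """P(v_i = 1 | h), vectorized over rows when h is 2-D."""
    h = np.asarray(h, dtype=float)
    return expit(h @ params.w + params.b)


def reconstruct(params: RBMParameters, v: np.ndarray) -> np.ndarray:
    """Deterministic mean-field reconstruction v -> P(h|v) -> P(v|h)."""
    return prob_v_given_h(params, prob_h_given_v(params, v))


def reconstruction_error(params: RBMParameters, data: np.ndarray) -> float:
    """Mean squared error of the mean-field reconstruction over data rows."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return float(np.mean((data - reconstruct(params, data)) ** 2))


# ---------------------------------------------------------------------------
# Contrastive divergence
# ---------------------------------------------------------------------------


def cd_update(
    params: RBMParameters,
    batch: np.ndarray,
    config: TrainConfig,
    rng: Optional[np.random.Generator] = None,
) -> RBMParameters:
    """One CD-k gradient-ascent step on a batch of visible rows.

    Random draws, in order: (1) Bernoulli sample of the data-phase hidden
    probabilities; then per intermediate Gibbs step a visible sample and a
    hidden sample. The final visible state is the mean-field probability
    and the negative-phase hidden statistics use probabilities, not
    samples. With ``rng=None`` a fresh generator is seeded from
    ``config.seed``, so identical (params, batch, config) give identical
    updates.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.size == 0:
        raise ValueError("batch must be non-empty")
    if batch.min() < 0 or batch.max() > 1:
        raise ValueError("visible values must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n = batch.shape[0]
    ph_data = prob_h_given_v(params, batch)
    h = (rng.random(ph_data.shape) < ph_data).astype(float)

    for step in range(1, config.cd_k + 1):
        pv = prob_v_given_h(params, h)
        if step < config.cd_k:
            v = (rng.random(pv.shape) < pv).astype(float)
            ph = prob_h_given_v(params, v)
            h = (rng.random(ph.shape) < ph).astype(float)
        else:
            v = pv  # mean-field final visible state
            ph = prob_h_given_v(params, v)

    lr = config.learning_rate
    w = params.w + lr * (ph_data.T @ batch - ph.T @ v) / n
    b = params.b + lr * (batch - v).mean(axis=0)
    d = params.d + lr * (ph_data - ph).mean(axis=0)
    if not all(np.all(np.isfinite(a)) for a in (w, b, d)):
        raise FloatingPointError(
            "non-finite CD update; try a smaller learning_rate"
        )
    return RBMParameters(w, b, d)


def train(
    params_init: RBMParameters,
    data: np.ndarray,
    config: TrainConfig,
) -> tuple[RBMParameters, list[float]]:
    """Train by epochs of shuffled mini-batch CD updates.

    Returns the trained parameters and the per-epoch mean-squared
    reconstruction error history (computed after each epoch). With
    ``epochs=0`` the initial parameters are returned untouched.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[1] != params_init.n_visible:
        raise ValueError("data width does not match visible layer size")
    rng = np.random.default_rng(config.seed)
    params = params_init.copy()
    history: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(data.shape[0])
        for start in range(0, data.shape[0], config.batch_size):
            batch = data[order[start : start + config.batch_size]]
            params = cd_update(params, batch, config, rng=rng)
        history.append(reconstruction_error(params, data))
    return params, history


# ---------------------------------------------------------------------------
# Exact enumeration (small models only)
# ---------------------------------------------------------------------------


def enumerate_states(n: int) -> np.ndarray:
    """All 2^n binary vectors of length n, lexicographic order."""
    return np.array(list(itertools.product((0.0, 1.0), repeat=n)))


def _check_enumerable(params: RBMParameters) -> None:
    if params.n_visible + params.n_hidden > 20:
        raise ValueError("exact enumeration limited to <= 20 total units")


def log_partition(params: RBMParameters) -> float:
    """log Z by summing exp E over every joint (v, h) state."""
    _check_enumerable(params)
    all_v = enumerate_states(params.n_visible)
    all_h = enumerate_states(params.n_hidden)
    e = all_h @ params.w @ all_v.T + (all_h @ params.d)[:, None]
    e = e + (all_v @ params.b)[None, :]
    return float(logsumexp(e))


def exact_log_likelihood(params: RBMParameters, data: np.ndarray) -> float:
    """Exact mean log P(v) over data rows (hidden units summed out)."""
    _check_enumerable(params)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    all_h = enumerate_states(params.n_hidden)
    e = all_h @ params.w @ data.T + (all_h @ params.d)[:, None]
    e = e + (data @ params.b)[None, :]
    log_unnorm = logsumexp(e, axis=0)
    return float(np.mean(log_unnorm) - log_partition(params))


def exact_visible_distribution(
    params: RBMParameters,
) -> tuple[np.ndarray, np.ndarray]:
    """All visible states and their exact marginal probabilities."""
    _check_enumerable(params)
    all_v = enumerate_states(params.n_visible)
    all_h = enumerate_states(params.n_hidden)
    e = all_h @ params.w @ all_v.T + (all_h @ params.d)[:, None]
    e = e + (all_v @ params.b)[None, :]
    log_unnorm = logsumexp(e, axis=0)
    return all_v, np.exp(log_unnorm - logsumexp(log_unnorm))
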