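"""Synthetic data with the structure the pipeline assumes.

The generator emulates a periodic expression experiment over a modular
interactome: genes belong to modules, each module's genes share a
periodic square-wave profile — a high plateau over half the cycle and a
low trough over the other half, with a module-specific phase (replicates
are independently noisy copies of one cycle). The static network is a
planted partition — dense within modules, sparse between.

The square wave rather than a raw sinusoid keeps the *activity duty
cycle* identical for every gene (high for exactly half the timepoints,
with expression far from the activity threshold on both sides), so
non-planted proteins realize the same instant neighborhood at every
timepoint they are active: the stable majority the reconstruction model
is supposed to explain. A sinusoid instead makes threshold crossings
marginal and gene-specific, so the duty cycle itself — not neighborhood
structure — becomes the dominant source of reconstruction-error
variability.

A chosen subset of proteins is then planted as *critical*: at a
per-protein switch timepoint their expression phase switches to another
module's phase (switch time and target module are chosen to preserve the
half-cycle duty), and edges into the target module are added alongside a
matching share of their own-module edges. Their instant neighborhoods
therefore rotate between modules across the course while everyone else's
stay consistent, giving a ground-truth list for recovery experiments.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from dynppi.io_formats import EdgeList, ExpressionMatrix


@dataclass
class SyntheticSpec:
    """Generator settings; defaults are desk-scale but structurally faithful.

    ``p_in``/``p_out`` default to an overall edge density of about 0.10
    with four equal modules. ``rewiring_strength`` in [0, 1] is both the
    fraction of a planted protein's module edges that move and the weight
    of the new phase in its post-switch expression; 0 disables planting.
    """

    n_proteins: int = 100
    n_timepoints: int = 12
    n_replicates: int = 3
    n_modules: int = 4
    n_critical: int = 10
    rewiring_strength: float = 1.0
    noise_sd: float = 0.1
    p_in: float = 0.35
    p_out: float = 0.01
    baseline: float = 3.0
    amplitude: float = 0.7
    texture_amplitude: float = 0.1
    switch_timepoint: Optional[int] = None  # default n_timepoints // 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_timepoints, self.n_replicates) < 1:
            raise ValueError("counts must be positive")
        if not 1 <= self.n_modules <= self.n_proteins:
            raise ValueError("n_modules must be in [1, n_proteins]")
        if not 0 <= self.n_critical <= self.n_proteins:
            raise ValueError("n_critical must be in [0, n_proteins]")
        if not 0.0 <= self.rewiring_strength <= 1.0:
            raise ValueError("rewiring_strength must be in [0, 1]")
        for p in (self.p_in, self.p_out):
            if not 0.0 <= p <= 1.0:
                raise ValueError("edge probabilities must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def switch_t(self) -> int:
        return (
            self.switch_timepoint
            if self.switch_timepoint is not None
            else self.n_timepoints // 2
        )

    def expected_density(self) -> float:
        """Expected overall edge density of the planted partition."""
        sizes = np.bincount(module_assignment(self), minlength=self.n_modules)
        within = float(sum(s * (s - 1) / 2 for s in sizes))
        total = self.n_proteins * (self.n_proteins - 1) / 2
        return (within * self.p_in + (total - within) * self.p_out) / total


def protein_ids(spec: SyntheticSpec) -> list[str]:
    return [f"P{i:04d}" for i in range(spec.n_proteins)]


def module_assignment(spec: SyntheticSpec) -> np.ndarray:
    """Contiguous-block module index for every protein."""
    return (np.arange(spec.n_proteins) * spec.n_modules) // spec.n_proteins


def _module_onset(spec: SyntheticSpec, module: int) -> int:
    """First high timepoint of a module's plateau.

    Onsets are spread evenly over the cycle and staggered half a
    phase-step off the course boundary, so no module's window coincides
    with either half of the course.
    """
    stagger = spec.n_timepoints // (2 * spec.n_modules)
    return int(round(module * spec.n_timepoints / spec.n_modules)) + stagger


def module_high_window(spec: SyntheticSpec, module: int) -> np.ndarray:
    """Timepoints at which the module's plateau is high (half the cycle)."""
    t_half = spec.n_timepoints // 2
    shifted = (np.arange(spec.n_timepoints) - _module_onset(spec, module)) % (
        spec.n_timepoints
    )
    return np.flatnonzero(shifted < t_half)


def _module_wave(spec: SyntheticSpec, module: int) -> np.ndarray:
    """+1 on the module's high window, -1 on its trough."""
    wave = -np.ones(spec.n_timepoints)
    wave[module_high_window(spec, module)] = 1.0
    return wave


def _module_profile(spec: SyntheticSpec, module: int) -> np.ndarray:
    """Noise-free expression of one module over the cycle.

    Square plateau/trough plus a small module-phased sinusoidal texture.
    The texture keeps within-module expression co-varying inside every
    correlation window (a bare plateau has no shared signal, so windowed
    Pearson correlations there would be estimated from noise alone); its
    amplitude is small enough not to carry plateau values across the
    activity threshold.
    """
    t = np.arange(spec.n_timepoints)
    onset = _module_onset(spec, module)
    theta = 2 * np.pi * (t - onset - spec.n_timepoints // 4) / spec.n_timepoints
    # two harmonics: the pair is never simultaneously flat, so every
    # correlation window sees some shared within-module gradient
    texture = spec.texture_amplitude * (np.sin(theta) + 0.7 * np.sin(2 * theta))
    return spec.baseline + spec.amplitude * _module_wave(spec, module) + texture


def _clean_profiles(spec: SyntheticSpec) -> np.ndarray:
    """Noise-free genes x timepoints profiles (textured square waves)."""
    modules = module_assignment(spec)
    profiles = np.stack(
        [_module_profile(spec, m) for m in range(spec.n_modules)]
    )
    return profiles[modules]


def generate_expression(spec: SyntheticSpec) -> ExpressionMatrix:
    """Periodic module-phased expression; replicates are noisy copies."""
    rng = np.random.default_rng([spec.seed, 0])
    clean = _clean_profiles(spec)
    values = clean[:, :, None] + rng.normal(
        0.0, spec.noise_sd, size=(spec.n_proteins, spec.n_timepoints, spec.n_replicates)
    )
    return ExpressionMatrix(protein_ids(spec), values)


def generate_static_ppin(spec: SyntheticSpec) -> EdgeList:
    """Planted-partition scaffold: p_in within modules, p_out between."""
    rng = np.random.default_rng([spec.seed, 1])
    ids = protein_ids(spec)
    modules = module_assignment(spec)
    same = modules[:, None] == modules[None, :]
    probs = np.where(same, spec.p_in, spec.p_out)
    draws = rng.random((spec.n_proteins, spec.n_proteins))
    iu, ju = np.triu_indices(spec.n_proteins, k=1)
    pairs = {
        (ids[i], ids[j])
        for i, j in zip(iu, ju)
        if draws[i, j] < probs[i, j]
    }
    return EdgeList(pairs)


def _switch_plan(spec: SyntheticSpec, module: int) -> tuple[int, int]:
    """Switch timepoint and target module for a planted protein.

    The composite profile (own phase before the switch, target phase
    after) realizes a high plateau one timepoint *shorter* than the
    half-cycle plateau of non-planted proteins where the window geometry
    allows it (the identity switch costs the protein part of both
    modules' windows — a transition downtime), split as unevenly as
    possible between the two phases so one module is the protein's
    dominant structure and the other a short-lived excursion. Where no
    such plan exists the duty stays at the half cycle.
    """
    t_half = spec.n_timepoints // 2
    own_high = set(module_high_window(spec, module).tolist())
    best: tuple | None = None
    for m2 in range(spec.n_modules):
        if m2 == module:
            continue
        other_high = set(module_high_window(spec, m2).tolist())
        for s_t in range(1, spec.n_timepoints):
            pre = len([t for t in own_high if t < s_t])
            post = len([t for t in other_high if t >= s_t])
            if pre == 0 or post == 0:
                continue  # not a real switch
            duty = pre + post
            if duty == t_half - 1:
                duty_rank = 0
            elif duty == t_half:
                duty_rank = 1
            else:
                duty_rank = 2 + abs(duty - t_half)
            key = (
                duty_rank,
                -abs(pre - post),
                abs(s_t - spec.switch_t),
                m2,
                s_t,
            )
            if best is None or key < best[:5]:
                best = (*key, s_t, m2)
    assert best is not None
    return best[5], best[6]


def plant_critical(
    spec: SyntheticSpec, expr: ExpressionMatrix, ppin: EdgeList
) -> tuple[ExpressionMatrix, EdgeList, list[str]]:
    """Plant structure-changing proteins; returns the ground-truth list.

    Each planted protein switches toward the module "opposite" its own at
    the switch timepoint: its expression blends to the target module's
    phase with weight equal to the rewiring strength, and for each of its
    within-module edges a new edge to a random target-module partner is
    added with that probability. The protein thus stays wired to both
    modules in the static scaffold, but the interactions it *realizes*
    rotate from its own module (active at its old phase, first half) to
    the target module (second half) — its instant neighborhood changes
    sharply across the course while non-planted neighborhoods stay
    consistent. Strength 0 (or zero planted count) returns the inputs
    unchanged.
    """
    s = spec.rewiring_strength
    if spec.n_critical == 0 or s == 0.0:
        return expr, ppin, []
    if spec.n_modules < 2:
        raise ValueError("planting requires at least 2 modules")

    rng = np.random.default_rng([spec.seed, 2])
    ids = protein_ids(spec)
    index = {p: i for i, p in enumerate(ids)}
    modules = module_assignment(spec)
    planted_idx = np.sort(rng.choice(spec.n_proteins, spec.n_critical, replace=False))
    switches = [
        _switch_plan(spec, int(modules[i])) for i in planted_idx
    ]
    targets = np.array([m2 for _, m2 in switches])

    # expression: switch to the target phase at the per-protein switch time
    values = expr.values.copy()
    t = np.arange(spec.n_timepoints)
    for i, (s_t, m2) in zip(planted_idx, switches):
        own = _module_profile(spec, int(modules[i]))
        other = _module_profile(spec, m2)
        clean = np.where(t < s_t, own, (1 - s) * own + s * other)
        values[i] = clean[:, None] + rng.normal(
            0.0, spec.noise_sd, size=(spec.n_timepoints, spec.n_replicates)
        )

    # edges: mirror each within-module edge of a planted protein into the
    # target module with probability s (originals are kept)
    pairs = set(ppin.pairs)
    planted_set = set(planted_idx.tolist())
    member_lists = [
        np.flatnonzero(modules == m) for m in range(spec.n_modules)
    ]
    for i, m2 in zip(planted_idx, targets):
        neighbors = [pair for pair in pairs if ids[i] in pair]
        for pair in neighbors:
            q = index[pair[0] if pair[1] == ids[i] else pair[1]]
            if modules[q] != modules[i] or q in planted_set:
                continue
            if rng.random() >= s:
                continue
            candidates = [
                c
                for c in member_lists[m2]
                if c != i
                and (min(ids[i], ids[c]), max(ids[i], ids[c])) not in pairs
            ]
            if not candidates:
                continue
            c = int(rng.choice(candidates))
            pairs.add((min(ids[i], ids[c]), max(ids[i], ids[c])))

    truth = [ids[i] for i in planted_idx]
    return (
        ExpressionMatrix(list(ids), values, list(expr.timepoint_labels)),
        EdgeList(pairs),
        truth,
    )


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, EdgeList, list[str]]:
    """Expression + scaffold + planted criticals in one call."""
    expr = generate_expression(spec)
    ppin = generate_static_ppin(spec)
    return plant_critical(spec, expr, ppin)


def with_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    return replace(spec, seed=seed)
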