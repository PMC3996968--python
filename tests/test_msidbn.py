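import itertools
import math

import numpy as np
import pytest

from dynppi import msidbn
from dynppi.dynamic_networks import NetworkSeries
from dynppi.msidbn import (
    JointLayer,
    MsiDBNModel,
    SourceStack,
    encode,
    pretrain_stacks,
    reconstruct,
    train_full,
    train_joint,
)
from dynppi.rbm import RBMParameters, TrainConfig, prob_h_given_v, train


def zero_model(n=4, h1=3, h2=2, j=2, t=2):
    stacks = [
        SourceStack(
            k,
            RBMParameters(np.zeros((h1, n)), np.zeros(n), np.zeros(h1)),
            RBMParameters(np.zeros((h2, h1)), np.zeros(h1), np.zeros(h2)),
        )
        for k in range(t)
    ]
    joint = JointLayer(
        RBMParameters(np.zeros((j, t * h2)), np.zeros(t * h2), np.zeros(j)),
        n_sources=t,
        block_size=h2,
    )
    return MsiDBNModel(stacks, joint, (n, h1, h2, j))


def toy_series(rng, n=12, t=3):
    mats = []
    for _ in range(t):
        m = rng.random((n, n))
        m = np.triu(m, 1) + np.triu(m, 1).T
        mats.append(m)
    return NetworkSeries([f"P{i:02d}" for i in range(n)], mats)


class TestPretrain:
    def test_identical_sources_give_identical_stacks(self, rng):
        m = rng.random((10, 10))
        m = np.triu(m, 1) + np.triu(m, 1).T
        series = NetworkSeries([f"P{i}" for i in range(10)], [m.copy() for _ in range(3)])
        stacks, _ = pretrain_stacks(series, (6, 4), TrainConfig(epochs=3, seed=2))
        for s in stacks[1:]:
            np.testing.assert_array_equal(s.layer1.w, stacks[0].layer1.w)
            np.testing.assert_array_equal(s.layer2.w, stacks[0].layer2.w)

    def test_single_source_reduces_to_plain_two_layer_pretrain(self, rng):
        series = toy_series(rng, n=10, t=1)
        cfg = TrainConfig(epochs=4, seed=5)
        stacks, _ = pretrain_stacks(series, (6, 4), cfg)
        init1 = RBMParameters.initialize(6, 10, cfg.init_scale, cfg.derive(0).seed)
        l1, _ = train(init1, series.matrices[0], cfg.derive(0))
        np.testing.assert_array_equal(stacks[0].layer1.w, l1.w)
        hidden = prob_h_given_v(l1, series.matrices[0])
        init2 = RBMParameters.initialize(4, 6, cfg.init_scale, cfg.derive(1).seed)
        l2, _ = train(init2, hidden, cfg.derive(1))
        np.testing.assert_array_equal(stacks[0].layer2.w, l2.w)

    def test_layer1_errors_decrease_for_every_stack(self, rng):
        series = toy_series(np.random.default_rng(0), n=30, t=3)
        _, log = pretrain_stacks(series, (20, 10), TrainConfig(epochs=40, seed=4))
        for hist in log["layer1_errors"]:
            assert hist[-1] < hist[0]

    def test_bad_sizes_rejected(self, rng):
        series = toy_series(rng)
        with pytest.raises(ValueError):
            pretrain_stacks(series, (0, 4), TrainConfig())


class TestJointLayer:
    def test_zero_weights_give_half_probabilities(self):
        model = zero_model()
        series = NetworkSeries(
            ["a", "b", "c", "d"], [np.zeros((4, 4)) for _ in range(2)]
        )
        np.testing.assert_allclose(encode(model, series), 0.5)

    def test_joint_size_must_be_positive(self, rng):
        series = toy_series(rng, n=8, t=2)
        stacks, _ = pretrain_stacks(series, (4, 3), TrainConfig(epochs=1, seed=0))
        with pytest.raises(ValueError):
            train_joint(stacks, series, 0, TrainConfig(epochs=1, seed=0))

    def test_conditionals_match_enumeration(self):
        """Shared-layer conditionals equal brute-force marginals.

        The joint layer is an RBM over the concatenated per-source h2
        blocks; its sigmoid conditionals must agree with enumerating all
        (h2, h) joint states under the exponential-family joint.
        """
        rng = np.random.default_rng(8)
        series = toy_series(rng, n=6, t=2)
        model = train_full(
            series, sizes=(4, 3), joint_size=2, config=TrainConfig(epochs=5, seed=8)
        )
        joint = model.joint.rbm  # visible 6 (= 2 sources x 3), hidden 2

        def joint_weight(x, h):
            e = h @ joint.w @ x + joint.d @ h + joint.b @ x
            return math.exp(e)

        for x_bits in itertools.islice(itertools.product((0, 1), repeat=6), 0, 64, 7):
            x = np.array(x_bits, dtype=float)
            denom, margin = 0.0, np.zeros(2)
            for h_bits in itertools.product((0, 1), repeat=2):
                h = np.array(h_bits, dtype=float)
                w = joint_weight(x, h)
                denom += w
                margin += w * h
            np.testing.assert_allclose(
                prob_h_given_v(joint, x), margin / denom, atol=1e-10
            )
        # downward block conditionals P(h2^(t) | h)
        for h_bits in itertools.product((0, 1), repeat=2):
            h = np.array(h_bits, dtype=float)
            denom = 0.0
            margin = np.zeros(6)
            for x_bits in itertools.product((0, 1), repeat=6):
                x = np.array(x_bits, dtype=float)
                w = joint_weight(x, h)
                denom += w
                margin += w * x
            expected = margin / denom
            for t in range(2):
                block = 1.0 / (
                    1.0 + np.exp(-(model.joint.d_block(t) + h @ model.joint.w3_block(t)))
                )
                np.testing.assert_allclose(block, expected[t * 3 : (t + 1) * 3], atol=1e-10)


class TestEncodeReconstruct:
    def test_zero_model_reconstruction_is_half(self):
        model = zero_model()
        series = NetworkSeries(
            ["a", "b", "c", "d"], [np.zeros((4, 4)) for _ in range(2)]
        )
        recon = reconstruct(model, series)
        for m in recon.matrices:
            np.testing.assert_allclose(m, 0.5)

    def test_mean_field_determinism(self, rng):
        series = toy_series(rng, n=10, t=2)
        model = train_full(series, sizes=(6, 4), joint_size=3, config=TrainConfig(epochs=3, seed=1))
        e1, e2 = encode(model, series), encode(model, series)
        np.testing.assert_array_equal(e1, e2)
        r1, r2 = reconstruct(model, series), reconstruct(model, series)
        for a, b in zip(r1.matrices, r2.matrices):
            np.testing.assert_array_equal(a, b)

    def test_reconstruction_in_open_unit_interval(self, rng):
        series = toy_series(rng, n=10, t=2)
        model = train_full(series, sizes=(6, 4), joint_size=3, config=TrainConfig(epochs=2, seed=1))
        for m in reconstruct(model, series).matrices:
            assert m.min() > 0.0 and m.max() < 1.0

    def test_sampled_reconstruction_is_seeded(self, rng):
        series = toy_series(rng, n=8, t=2)
        model = train_full(series, sizes=(5, 3), joint_size=2, config=TrainConfig(epochs=2, seed=1))
        r1 = reconstruct(model, series, sample=True, seed=4)
        r2 = reconstruct(model, series, sample=True, seed=4)
        for a, b in zip(r1.matrices, r2.matrices):
            np.testing.assert_array_equal(a, b)

    def test_size_mismatch_rejected(self, rng):
        series = toy_series(rng, n=10, t=2)
        model = train_full(series, sizes=(6, 4), joint_size=3, config=TrainConfig(epochs=1, seed=1))
        other = toy_series(rng, n=10, t=3)
        with pytest.raises(ValueError, match="sources"):
            reconstruct(model, other)
        smaller = toy_series(rng, n=6, t=2)
        with pytest.raises(ValueError, match="proteins"):
            encode(model, smaller)

    def test_source_permutation_of_identical_sources(self, rng):
        m = rng.random((8, 8))
        m = np.triu(m, 1) + np.triu(m, 1).T
        series = NetworkSeries([f"P{i}" for i in range(8)], [m.copy(), m.copy()])
        permuted = NetworkSeries([f"P{i}" for i in range(8)], [m.copy(), m.copy()])
        cfg = TrainConfig(epochs=3, seed=9)
        e1 = encode(train_full(series, sizes=(5, 3), joint_size=2, config=cfg), series)
        e2 = encode(train_full(permuted, sizes=(5, 3), joint_size=2, config=cfg), permuted)
        np.testing.assert_array_equal(e1, e2)

    def test_encoding_separates_planted_groups(self):
        rng = np.random.default_rng(1)
        n = 30
        block = np.zeros((n, n))
        block[:15, :15] = 0.8
        block[15:, 15:] = 0.8
        mats = []
        for _ in range(3):
            m = np.clip(block + rng.normal(0, 0.05, (n, n)), 0, 1)
            mats.append(np.triu(m, 1) + np.triu(m, 1).T)
        series = NetworkSeries([f"P{i}" for i in range(n)], mats)
        model = train_full(series, sizes=(16, 8), joint_size=4, config=TrainConfig(seed=1, epochs=100))
        enc = encode(model, series)
        c1, c2 = enc[:15].mean(axis=0), enc[15:].mean(axis=0)
        between = np.linalg.norm(c1 - c2)
        within = 0.5 * (
            np.linalg.norm(enc[:15] - c1, axis=1).mean()
            + np.linalg.norm(enc[15:] - c2, axis=1).mean()
        )
        assert between > within


class TestTrainFull:
    def test_end_to_end_invariants(self, rng):
        series = toy_series(np.random.default_rng(3), n=40, t=4)
        model = train_full(series, sizes=(20, 10), joint_size=5, config=TrainConfig(epochs=5, seed=3))
        assert model.layer_sizes == (40, 20, 10, 5)
        assert model.n_sources == 4
        assert len(model.training_log["joint_errors"]) == 5

    def test_zero_epochs_still_reconstructs(self, rng):
        series = toy_series(rng, n=10, t=2)
        model = train_full(series, sizes=(6, 4), joint_size=3, config=TrainConfig(epochs=0, seed=0))
        for m in reconstruct(model, series).matrices:
            assert np.all((m > 0) & (m < 1))

    def test_default_sizes_follow_n(self, rng):
        assert msidbn.default_layer_sizes(100) == (100, 100, 32)
        assert msidbn.default_layer_sizes(500) == (256, 128, 32)
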