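import numpy as np
import pytest

from dynppi.dynamic_networks import (
    activity_network,
    binarize_activity,
    build_series,
    combine_networks,
    compute_activity_scores,
    higher_order,
    series_stats,
    validate_series,
    windowed_coexpression,
)
from dynppi.io_formats import EdgeList

from conftest import make_expression


class TestActivityScores:
    def test_zero_variance_reduces_to_mean_in_both_forms(self):
        expr = make_expression([[2.0, 2.0, 2.0]])
        for form in ("range_consistent", "eq1_literal"):
            model = compute_activity_scores(expr, alpha=1.5, form=form)
            assert model.ac_score[0] == pytest.approx(2.0)

    def test_range_consistent_hand_value(self):
        # pooled values (0,1,2): mu=1, sample sigma=1
        expr = make_expression([[0.0, 1.0, 2.0]])
        model = compute_activity_scores(expr, alpha=1.5, form="range_consistent")
        assert model.mu[0] == pytest.approx(1.0)
        assert model.sigma[0] == pytest.approx(1.0)
        # mu + alpha * sigma^3 / (1 + sigma^2) = 1 + 1.5/2
        assert model.ac_score[0] == pytest.approx(1.75)

    def test_literal_form_hand_value(self):
        expr = make_expression([[0.0, 1.0, 2.0]])
        model = compute_activity_scores(expr, alpha=1.5, form="eq1_literal")
        # F = 1/(1+sigma) = 0.5; thr1*F + thr2*(1-F) = 1*0.5 + 1*0.5
        assert model.f[0] == pytest.approx(0.5)
        assert model.ac_score[0] == pytest.approx(1.0)

    def test_alpha_must_be_positive(self):
        expr = make_expression([[0.0, 1.0, 2.0]])
        with pytest.raises(ValueError, match="alpha"):
            compute_activity_scores(expr, alpha=0.0)

    def test_reference_pooling_shifts_mean(self):
        expr = make_expression([[1.0, 1.0, 1.0]], gene_ids=["G0"])
        ref = make_expression([[3.0, 3.0, 3.0]], gene_ids=["G0"])
        model = compute_activity_scores(expr, reference=ref)
        assert model.mu[0] == pytest.approx(2.0)

    def test_disjoint_reference_is_error(self):
        expr = make_expression([[1.0, 2.0]], gene_ids=["G0"])
        ref = make_expression([[1.0, 2.0]], gene_ids=["OTHER"])
        with pytest.raises(ValueError, match="reference"):
            compute_activity_scores(expr, reference=ref)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_active_count_monotone_in_alpha(self, seed):
        rng = np.random.default_rng(seed)
        expr = make_expression(rng.normal(5, 1, size=(30, 10, 2)))
        counts = []
        for alpha in (0.5, 1.5, 3.0):
            model = compute_activity_scores(expr, alpha=alpha)
            counts.append(
                sum(
                    binarize_activity(expr, model, t).sum()
                    for t in range(expr.n_timepoints)
                )
            )
        assert counts[0] >= counts[1] >= counts[2]


class TestBinarizeAndActivityNetwork:
    def test_threshold_is_inclusive(self):
        expr = make_expression([[2.0, 0.0, 4.0]])  # mu=2 at t=0 g=2
        model = compute_activity_scores(expr)
        model.ac_score[:] = 2.0
        assert binarize_activity(expr, model, 0)[0] == 1.0

    def test_two_protein_toy(self):
        expr = make_expression([[3.0, 3.0], [1.0, 1.0]])
        model = compute_activity_scores(expr)
        model.ac_score[:] = [2.0, 2.0]
        np.testing.assert_array_equal(binarize_activity(expr, model, 0), [1.0, 0.0])

    def test_outer_product_pattern(self):
        act = activity_network(np.array([1.0, 0.0, 1.0]))
        expected = np.zeros((3, 3))
        expected[np.ix_([0, 2], [0, 2])] = 1.0
        np.testing.assert_array_equal(act, expected)

    def test_zero_and_ones_limits(self):
        np.testing.assert_array_equal(activity_network(np.zeros(4)), np.zeros((4, 4)))
        np.testing.assert_array_equal(
            activity_network(np.ones(3)), np.ones((3, 3))
        )

    def test_rank_one_idempotence(self, rng):
        delta = (rng.random(10) < 0.5).astype(float)
        act = activity_network(delta)
        assert np.linalg.matrix_rank(act) <= 1
        np.testing.assert_allclose(act @ act, delta.sum() * act)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            activity_network(np.array([0.5, 1.0]))


class TestWindowedCoexpression:
    def test_identical_profiles_give_one(self):
        expr = make_expression([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        coe = windowed_coexpression(expr, 1)
        assert coe[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_profiles_give_zero(self):
        expr = make_expression([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        coe = windowed_coexpression(expr, 1)
        assert coe[0, 1] == pytest.approx(0.0)

    def test_hand_computed_pearson(self):
        expr = make_expression([[1.0, 2.0, 3.0], [1.0, 2.0, 4.0]])
        coe = windowed_coexpression(expr, 1)
        r = 9.0 / np.sqrt(84.0)  # Pearson of (1,2,3) vs (1,2,4)
        assert coe[0, 1] == pytest.approx((r + 1) / 2, abs=1e-9)
        assert coe[0, 1] == pytest.approx(0.99099, abs=1e-5)

    def test_constant_profile_pairs_get_half(self):
        expr = make_expression([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        coe = windowed_coexpression(expr, 1)
        assert coe[0, 1] == pytest.approx(0.5)
        assert coe[0, 0] == pytest.approx(0.5)  # constant self
        assert coe[1, 1] == pytest.approx(1.0)  # non-constant self

    def test_bounds_and_symmetry(self, rng):
        expr = make_expression(rng.normal(size=(8, 6, 2)))
        for t in range(6):
            coe = windowed_coexpression(expr, t)
            np.testing.assert_allclose(coe, coe.T)
            assert coe.min() >= 0.0 and coe.max() <= 1.0

    def test_circular_wrap_uses_last_timepoint(self, rng):
        values = rng.normal(size=(5, 6, 2))
        expr = make_expression(values)
        shifted = make_expression(np.roll(values, 1, axis=1))
        np.testing.assert_allclose(
            windowed_coexpression(expr, 0), windowed_coexpression(shifted, 1)
        )

    def test_too_few_samples_is_error(self):
        expr = make_expression(np.ones((2, 2, 1)))
        with pytest.raises(ValueError, match="window|timepoints"):
            windowed_coexpression(expr, 0, half_width=0)


class TestCombineAndHigherOrder:
    def test_zero_ppi_absorbs_everything(self, rng):
        n = 4
        coe, act = rng.random((n, n)), np.ones((n, n))
        out = combine_networks(coe, act, np.zeros((n, n)))
        np.testing.assert_array_equal(out, np.zeros((n, n)))

    def test_single_edge_weight(self):
        coe = np.full((2, 2), 0.5)
        act = np.ones((2, 2))
        ppi = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = combine_networks(coe, act, ppi)
        assert out[0, 1] == pytest.approx(0.5)
        assert out[0, 0] == 0.0

    def test_shape_mismatch_and_bad_ppi(self):
        with pytest.raises(ValueError, match="shapes"):
            combine_networks(np.ones((2, 2)), np.ones((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="binary"):
            combine_networks(np.ones((2, 2)), np.ones((2, 2)), np.full((2, 2), 0.5))

    def test_path_graph_square(self):
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        out = higher_order(a, order=2, rescale="none")
        assert out[0, 2] == 1.0 and out[2, 0] == 1.0
        np.testing.assert_array_equal(np.diag(out), np.zeros(3))

    def test_zero_matrix_unchanged(self):
        np.testing.assert_array_equal(
            higher_order(np.zeros((3, 3))), np.zeros((3, 3))
        )

    def test_order_one_no_rescale_zeroes_diagonal(self):
        a = np.array([[1.0, 0.3], [0.3, 1.0]])
        out = higher_order(a, order=1, rescale="none")
        np.testing.assert_array_equal(out, np.array([[0.0, 0.3], [0.3, 0.0]]))

    def test_max_rescale_bounds(self, rng):
        a = rng.random((6, 6))
        a = np.triu(a, 1) + np.triu(a, 1).T
        out = higher_order(a, order=2, rescale="max")
        assert 0.0 <= out.min() and out.max() == pytest.approx(1.0)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            higher_order(np.zeros((2, 2)), order=0)


class TestBuildSeries:
    def test_synthetic_series_invariants(self, small_series):
        validate_series(small_series, symmetric=True, unit_interval=True)
        assert small_series.n_timepoints == 8

    def test_mask_conservation(self, small_dataset):
        expr, edges, _ = small_dataset
        shared = [g for g in expr.gene_ids if g in set(edges.proteins())]
        sub = expr.subset(shared)
        ppi = edges.to_adjacency(shared)
        model = compute_activity_scores(sub)
        for t in range(sub.n_timepoints):
            a_t = combine_networks(
                windowed_coexpression(sub, t),
                activity_network(binarize_activity(sub, model, t)),
                ppi,
            )
            assert np.all(a_t[ppi == 0] == 0)

    def test_disjoint_gene_sets_error(self):
        expr = make_expression(np.ones((2, 4, 1)), gene_ids=["G0", "G1"])
        edges = EdgeList({("X", "Y")})
        with pytest.raises(ValueError, match="intersection"):
            build_series(expr, edges)

    def test_always_active_perfect_coe_reduces_to_ppi_square(self):
        # identical mildly varying profiles: every pairwise r is exactly 1
        # and the literal-form threshold sits below the minimum expression
        profile = np.array([9.5, 10.0, 10.5, 10.0])
        expr = make_expression(np.tile(profile, (6, 1)), gene_ids=[f"G{i}" for i in range(6)])
        edges = EdgeList({("G0", "G1"), ("G1", "G2"), ("G2", "G3"), ("G3", "G4"), ("G4", "G5"), ("G0", "G5")})
        series = build_series(expr, edges, form="eq1_literal", order=2)
        ppi = edges.to_adjacency(series.protein_ids)
        expected = np.linalg.matrix_power(ppi, 2)
        np.fill_diagonal(expected, 0.0)
        expected /= expected.max()
        for mat in series.matrices:
            np.testing.assert_allclose(mat, expected, atol=1e-12)

    def test_series_stats_counts(self, small_dataset):
        expr, edges, _ = small_dataset
        stats = series_stats(expr, edges)
        assert len(stats) == expr.n_timepoints
        for row in stats:
            assert 0 <= row["active_proteins"] <= 24
            assert row["interactions"] >= 0
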