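"""Sparseness machinery, update rules, and the full factorization loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bingo_unmix as bu
from bingo_unmix.solver import _project_rows


def plain_config(**kw):
    """Config with the soft penalty and phases disabled unless overridden —
    isolates the primitive update contracts."""
    base = dict(sp_h=0.3, alpha=0.0, constraint_iter=0, anneal_iter=0)
    base.update(kw)
    return bu.SolverConfig(**base)


class TestRowSparseness:
    def test_one_hot_is_one(self):
        assert bu.row_sparseness(np.array([0.0, 1.0, 0.0, 0.0])) == pytest.approx(1.0)

    def test_uniform_is_zero(self):
        assert bu.row_sparseness(np.full(4, 3.7)) == pytest.approx(0.0, abs=1e-12)

    def test_half_support_value(self):
        # n=4, L1=2, L2=sqrt(2): (2 - sqrt(2)) / (2 - 1)
        assert bu.row_sparseness(np.array([1.0, 1.0, 0.0, 0.0])) == pytest.approx(
            2.0 - np.sqrt(2.0)
        )

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**16), scale=st.floats(0.01, 100.0))
    def test_scale_invariant_and_bounded(self, seed, scale):
        v = np.random.default_rng(seed).random(6) + 1e-6
        s = bu.row_sparseness(v)
        assert 0.0 <= s <= 1.0
        assert bu.row_sparseness(scale * v) == pytest.approx(s, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            bu.row_sparseness(np.zeros(4))
        with pytest.raises(ValueError):
            bu.row_sparseness(np.array([1.0]))


class TestHoyerProject:
    def test_fixed_point(self):
        v = np.array([3.0, 1.0, 0.5, 0.0])
        out = bu.hoyer_project(v, float(v.sum()), float(np.linalg.norm(v)))
        np.testing.assert_allclose(out, v, atol=1e-12)

    def test_hits_requested_norms_on_random_vectors(self):
        rng = np.random.default_rng(0)
        n = 8
        for _ in range(100):
            v = rng.random(n)
            l2 = 1.0
            l1 = bu.sparseness_to_l1(0.5, l2, n)
            out = bu.hoyer_project(v, l1, l2)
            assert out.min() >= 0
            assert np.abs(out).sum() == pytest.approx(l1, rel=1e-9)
            assert np.linalg.norm(out) == pytest.approx(l2, rel=1e-9)
            assert bu.row_sparseness(out) == pytest.approx(0.5, abs=1e-6)

    def test_nonnegative_for_adversarial_input(self):
        v = np.array([-5.0, 2.0, -0.1, 0.4, -3.0])
        out = bu.hoyer_project(v, 1.5, 1.0)
        assert out.min() >= 0.0

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            bu.hoyer_project(np.ones(4), 0.5, 1.0)  # L1 < L2
        with pytest.raises(ValueError, match="infeasible"):
            bu.hoyer_project(np.ones(4), 3.0, 0.0)  # zero L2


class TestObjective:
    def test_exact_factorization_zero(self):
        rng = np.random.default_rng(0)
        W = rng.random((6, 2))
        H = rng.random((2, 4))
        total, fid, pen = bu.objective(W @ H, W, H, plain_config())
        assert total == pytest.approx(0.0, abs=1e-20)
        assert fid == total and pen == 0.0

    def test_alpha_zero_total_is_fidelity(self):
        rng = np.random.default_rng(1)
        X, W, H = rng.random((5, 3)), rng.random((5, 2)), rng.random((2, 3))
        total, fid, pen = bu.objective(X, W, H, plain_config())
        assert pen == 0.0
        assert total == pytest.approx(np.linalg.norm(X - W @ H) ** 2)

    def test_rows_at_target_give_zero_penalty(self):
        n = 4
        sp = 0.45
        H = np.stack(
            [
                bu.hoyer_project(v, bu.sparseness_to_l1(sp, 1.0, n), 1.0)
                for v in np.random.default_rng(2).random((3, n))
            ]
        )
        W = np.random.default_rng(3).random((6, 3))
        X = W @ H
        for form in ("linear", "squared"):
            cfg = plain_config(sp_h=sp, alpha=5.0, penalty_form=form)
            total, fid, pen = bu.objective(X, W, H, cfg)
            assert pen == pytest.approx(0.0, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bu.objective(np.ones((4, 3)), np.ones((4, 2)), np.ones((3, 3)), plain_config())


class TestUpdateH:
    def test_stationary_at_exact_factorization(self):
        rng = np.random.default_rng(4)
        W = rng.random((8, 2))
        H = rng.random((2, 5))
        H_next, step = bu.update_H(W @ H, W, H, plain_config(enforce_floor=False))
        np.testing.assert_allclose(H_next, H, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_never_increases(self, seed):
        rng = np.random.default_rng(seed)
        X, W, H = rng.random((10, 4)), rng.random((10, 3)), rng.random((3, 4))
        cfg = plain_config(sp_h=0.2, alpha=0.5)
        before = bu.objective(X, W, H, cfg)[0]
        H_next, _ = bu.update_H(X, W, H, cfg)
        after = bu.objective(X, W, H_next, cfg)[0]
        assert after <= before + 1e-12
        assert H_next.min() >= 0

    def test_floor_lifts_row_to_target(self):
        rng = np.random.default_rng(5)
        W = rng.random((10, 2))
        H = np.vstack([np.full(5, 0.8), rng.random(5) + 0.5])
        H[0, 0] = 1.0  # row 0 nearly uniform: sparseness well below 0.4
        assert bu.row_sparseness(H[0]) < 0.4
        cfg = plain_config(sp_h=0.4)
        H_next, _ = bu.update_H(W @ H, W, H, cfg)
        assert bu.row_sparseness(H_next[0]) == pytest.approx(0.4, abs=1e-6)

    def test_exact_projection_pins_all_rows(self):
        rng = np.random.default_rng(6)
        X, W, H = rng.random((10, 5)), rng.random((10, 3)), rng.random((3, 5))
        H_next, _ = bu.update_H(X, W, H, plain_config(sp_h=0.5), exact=True)
        for row in H_next:
            assert bu.row_sparseness(row) == pytest.approx(0.5, abs=1e-6)


class TestUpdateW:
    def test_fixed_point_at_exact_factorization(self):
        rng = np.random.default_rng(7)
        W = rng.random((6, 2)) + 0.1
        H = rng.random((2, 4)) + 0.1
        W_next = bu.update_W(W @ H, W, H)
        np.testing.assert_allclose(W_next, W, atol=1e-9)

    def test_zero_rows_stay_zero(self):
        rng = np.random.default_rng(8)
        W = rng.random((6, 2))
        W[3] = 0.0
        H = rng.random((2, 4))
        W_next = bu.update_W(rng.random((6, 4)), W, H)
        assert (W_next[3] == 0).all()

    def test_monotone_over_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            X = rng.random((8, 5))
            W = rng.random((8, 3))
            H = rng.random((3, 5))
            W_next = bu.update_W(X, W, H)
            assert np.linalg.norm(X - W_next @ H) <= np.linalg.norm(X - W @ H) + 1e-12
            assert W_next.min() >= 0


class TestBingoUnmix:
    def test_blind_recovery_on_noiseless_strips(self, noiseless_three_color_result):
        result, report = noiseless_three_color_result
        assert np.max(report.sad_per_component) < 0.05
        assert report.ssim_mean > 0.98
        assert report.rmse < 1e-3

    def test_result_invariants(self, noiseless_three_color_result):
        result, _ = noiseless_three_color_result
        assert result.W.min() >= 0 and result.H.min() >= 0
        np.testing.assert_allclose(result.H.max(axis=1), 1.0)
        peaks = np.argmax(result.H, axis=1)
        assert (np.diff(peaks) >= 0).all()
        fid = np.linalg.norm(result.X - result.W @ result.H) ** 2
        # the final trace value is fidelity plus the (annealed-away) penalty:
        # the remnant is nonnegative and negligible against the initial value
        gap = result.objective_trace[-1] - fid
        assert -1e-12 <= gap <= 1e-4 * result.objective_trace[0]

    def test_two_runs_bit_identical(self, noisy_three_color):
        _, _, stack, _ = noisy_three_color
        cfg = bu.SolverConfig(max_iter=80)
        r1 = bu.bingo_unmix(stack, 3, cfg)
        r2 = bu.bingo_unmix(stack, 3, cfg)
        np.testing.assert_array_equal(r1.W, r2.W)
        np.testing.assert_array_equal(r1.H, r2.H)
        np.testing.assert_array_equal(r1.objective_trace, r2.objective_trace)

    def test_sparseness_floor_holds_each_iteration(self, noisy_three_color):
        _, _, stack, _ = noisy_three_color
        sp = 0.35
        cfg = bu.SolverConfig(sp_h=sp, max_iter=60, constraint_iter=20, anneal_iter=10)
        X = bu.flatten(stack).values
        X = X / X.max()
        W, H = bu.nndsvd(X, 3)
        H = _project_rows(H, sp, exact=True)
        alpha = cfg.resolved_alpha(X.shape[0])
        for it in range(1, cfg.max_iter + 1):
            H, _ = bu.update_H(X, W, H, cfg, exact=it <= cfg.constraint_iter, alpha=alpha)
            W = bu.update_W(X, W, H)
            for row in H:
                if np.any(row):
                    assert bu.row_sparseness(row) >= sp - 1e-6

    def test_determined_system_precondition(self, noisy_three_color):
        _, _, stack, _ = noisy_three_color
        with pytest.raises(ValueError, match="determined"):
            bu.bingo_unmix(stack, 4)

    def test_all_zero_stack_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            bu.bingo_unmix(bu.ImageStack(np.zeros((3, 8, 8))), 2)


class TestSpTargets:
    def test_estimate_tracks_reference_sparseness(self, noiseless_three_color):
        _, _, stack, mixing = noiseless_three_color
        X = bu.flatten(stack).values
        est = bu.estimate_sp_h(X, margin=0.0)
        ref = bu.matrix_sparseness(mixing.values)
        assert est == pytest.approx(ref, abs=0.1)

    def test_suggest_is_slightly_below_reference(self, noiseless_three_color):
        _, _, _, mixing = noiseless_three_color
        assert bu.suggest_sp_h(mixing) == pytest.approx(
            bu.matrix_sparseness(mixing.values) - 0.05
        )


class TestSubtractCrosstalk:
    def test_zero_donor_leaves_target(self):
        rng = np.random.default_rng(0)
        target = rng.random((6, 6))
        out = bu.subtract_crosstalk([target, np.zeros((6, 6))], 0, [1])
        np.testing.assert_array_equal(out[0], target)

    def test_proportional_donor_cancels_exactly(self):
        rng = np.random.default_rng(1)
        donor = rng.random((6, 6))
        out = bu.subtract_crosstalk([0.7 * donor, donor], 0, [1])
        np.testing.assert_allclose(out[0], 0.0, atol=1e-9)
        np.testing.assert_array_equal(out[1], donor)

    def test_result_never_negative(self):
        rng = np.random.default_rng(2)
        images = [rng.random((5, 5)) for _ in range(3)]
        out = bu.subtract_crosstalk(images, 0, [1, 2])
        assert out[0].min() >= 0

    def test_identical_donor_rejected(self):
        im = np.random.default_rng(3).random((4, 4))
        with pytest.raises(ValueError, match="identical"):
            bu.subtract_crosstalk([im, im.copy()], 0, [1])
        with pytest.raises(ValueError, match="distinct"):
            bu.subtract_crosstalk([im, 2 * im], 0, [0])


class TestLinearUnmixingBaseline:
    def test_exact_on_noiseless_consistent_system(self, noiseless_three_color):
        _, phantom, stack, mixing = noiseless_three_color
        images = bu.lu_baseline(stack, mixing)
        for est, truth in zip(images, phantom.truths):
            np.testing.assert_allclose(est, truth, atol=1e-6)

    def test_one_hot_mixing_returns_raw_channels(self):
        rng = np.random.default_rng(4)
        stack = bu.ImageStack(rng.random((3, 5, 5)))
        S = bu.MixingMatrix(np.eye(3), (1.0, 1.0, 1.0))
        images = bu.lu_baseline(stack, S)
        np.testing.assert_allclose(np.stack(images), stack.channels, atol=1e-12)

    def test_zero_pixels_stay_zero(self):
        channels = np.random.default_rng(5).random((2, 4, 4))
        channels[:, 0, 0] = 0.0
        S = bu.MixingMatrix(np.array([[1.0, 0.4], [0.3, 1.0]]), (1.0, 1.0))
        images = bu.lu_baseline(bu.ImageStack(channels), S)
        assert images[0][0, 0] == 0.0 and images[1][0, 0] == 0.0

    def test_rank_deficient_mixing_names_rows(self):
        S = np.array([[1.0, 0.5, 0.1], [2.0, 1.0, 0.2], [0.0, 0.3, 1.0]])
        stack = bu.ImageStack(np.random.default_rng(6).random((3, 4, 4)))
        with pytest.raises(ValueError, match=r"rank-deficient.*\[0, 1\]"):
            bu.lu_baseline(stack, S)
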