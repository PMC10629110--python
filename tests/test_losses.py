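"""Hand-evaluated loss values, identities, and the uncertainty optimum."""

import numpy as np
import pytest

from msanet import (
    NetworkConfig,
    UncertaintyParams,
    ce_loss,
    dice_loss,
    focal_loss,
    joint_loss,
    seg_loss,
)
from msanet.nn import Tensor


class TestDiceLoss:
    def test_perfect_binary_prediction_is_near_zero(self):
        y = np.zeros((8, 8))
        y[2:5, 2:5] = 1
        assert dice_loss(y, y, epsilon=1e-6) == pytest.approx(0.0, abs=1e-6)

    def test_all_background_prediction_scores_one(self):
        y = np.zeros((8, 8))
        y[2:5, 2:5] = 1
        assert dice_loss(np.zeros_like(y), y, epsilon=1e-6) == pytest.approx(1.0)

    def test_hand_value_half_probabilities(self):
        # p = [0.5, 0.5], y = [1, 0], eps = 0: 1 - (2*0.5)/(0.5+0.5+1) = 0.5
        assert dice_loss(np.array([0.5, 0.5]), np.array([1.0, 0.0]),
                         epsilon=0.0) == pytest.approx(0.5, abs=1e-9)

    def test_monotone_in_true_foreground_probability(self):
        y = np.array([1.0, 0.0, 1.0])
        base = np.array([0.3, 0.2, 0.6])
        losses = []
        for bump in np.linspace(0, 0.7, 8):
            p = base.copy()
            p[0] = min(1.0, base[0] + bump)
            losses.append(dice_loss(p, y, 1e-6))
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_range_and_validation(self):
        with pytest.raises(ValueError, match="shape"):
            dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            dice_loss(np.array([1.5]), np.array([1.0]))


class TestFocalLoss:
    def test_perfect_confidence_gives_zero(self):
        y = np.array([1.0, 0.0])
        p = np.array([1.0, 0.0])
        assert focal_loss(p, y) == pytest.approx(0.0, abs=1e-5)

    def test_hand_value_single_foreground_pixel(self):
        # alpha (1-p)^gamma (-log p) = 0.8 * 0.25 * log 2 = 0.138629...
        got = focal_loss(np.array([0.5]), np.array([1.0]), alpha=0.8, gamma=2.0)
        assert got == pytest.approx(0.8 * 0.25 * np.log(2.0), abs=1e-6)

    def test_gamma_zero_alpha_balanced_is_summed_cross_entropy(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.05, 0.95, size=(6, 6))
        y = (rng.random((6, 6)) < 0.3).astype(float)
        got = focal_loss(p, y, alpha=0.5, gamma=0.0)
        ce = -(y * np.log(p) + (1 - y) * np.log(1 - p)).sum()
        assert got == pytest.approx(0.5 * ce, rel=1e-9)

    def test_sum_not_mean_scaling(self):
        p = np.full(100, 0.5)
        y = np.ones(100)
        assert focal_loss(p, y) == pytest.approx(100 * focal_loss(p[:1], y[:1]),
                                                 rel=1e-9)

    def test_zero_probability_is_floored_not_raised(self):
        val = focal_loss(np.array([0.0]), np.array([1.0]))
        assert np.isfinite(val) and val > 0


class TestSegLoss:
    def test_beta_combination_identity(self):
        rng = np.random.default_rng(6)
        cfg = NetworkConfig()
        p = rng.uniform(0.01, 0.99, size=(12, 12))
        y = (rng.random((12, 12)) < 0.2).astype(float)
        l_gtv, l_dice, l_focal = seg_loss(p, y, cfg)
        assert l_gtv == pytest.approx(l_dice + l_focal / 25000.0, abs=1e-9)

    def test_paper_scale_arithmetic(self):
        # l_dice 0.5 and l_focal 25000 must combine to 1.5 at beta = 1/25000
        cfg = NetworkConfig()
        assert 0.5 + cfg.focal_scale_beta * 25000.0 == pytest.approx(1.5)

    def test_beta_zero_reduces_to_dice(self):
        cfg = NetworkConfig(focal_scale_beta=0.0)
        p = np.array([0.5, 0.5])
        y = np.array([1.0, 0.0])
        l_gtv, l_dice, _ = seg_loss(p, y, cfg)
        assert l_gtv == pytest.approx(l_dice)


class TestCeLoss:
    def test_uniform_prediction(self):
        assert ce_loss(np.array([0.5, 0.5]), 1) == pytest.approx(np.log(2.0))

    def test_confident_wrong_prediction(self):
        assert ce_loss(np.array([0.9, 0.1]), 1) == pytest.approx(-np.log(0.1),
                                                                 abs=1e-9)

    def test_perfect_prediction_and_batch_mean(self):
        q = np.array([[1.0, 0.0], [0.5, 0.5]])
        got = ce_loss(q, np.array([0, 1]))
        assert got == pytest.approx(0.5 * np.log(2.0), abs=1e-5)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ce_loss(np.array([0.7, 0.6]), 0)


class TestJointLoss:
    def test_unit_sigmas_average_the_tasks(self):
        u = UncertaintyParams()
        assert joint_loss(1.0, 1.0, u) == pytest.approx(1.0, abs=1e-9)

    def test_hand_value_mixed_sigmas(self):
        u = UncertaintyParams(sigma_gtv=1.0, sigma_egfr=2.0)
        # 0.5 + 1/8 + log 2 = 1.3181471...
        assert joint_loss(1.0, 1.0, u) == pytest.approx(0.625 + np.log(2.0),
                                                        abs=1e-6)

    def test_equal_mode_is_fixed_half_half(self):
        assert joint_loss(0.8, 0.4, mode="equal") == pytest.approx(0.6, abs=1e-12)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            UncertaintyParams(sigma_gtv=0.0)

    def test_optimum_sigma_squared_equals_task_loss(self):
        """Minimizing L/(2s^2) + log s over sigma lands at sigma^2 = L."""
        for l_task in (0.25, 1.0, 4.0):
            grid = np.linspace(0.05, 5.0, 20000)
            vals = l_task / (2 * grid ** 2) + np.log(grid)
            assert grid[np.argmin(vals)] ** 2 == pytest.approx(l_task, rel=1e-2)
            # and the analytic first-order condition agrees
            sigma = np.sqrt(l_task)
            deriv = -l_task / sigma ** 3 + 1.0 / sigma
            assert deriv == pytest.approx(0.0, abs=1e-12)

    def test_gradient_wrt_sigma_matches_finite_difference(self):
        u = UncertaintyParams(sigma_gtv=1.3, sigma_egfr=0.7)
        l_g, l_e = Tensor(np.array(0.9)), Tensor(np.array(0.4))
        out = joint_loss(l_g, l_e, u)
        out.backward()
        eps = 1e-6
        for s in (u.s_gtv, u.s_egfr):
            orig = s.data.copy()
            s.data = orig + eps
            fp = float(joint_loss(Tensor(l_g.data), Tensor(l_e.data), u).data)
            s.data = orig - eps
            fm = float(joint_loss(Tensor(l_g.data), Tensor(l_e.data), u).data)
            s.data = orig
            assert float(s.grad) == pytest.approx((fp - fm) / (2 * eps), abs=1e-4)


def test_tensor_path_matches_numpy_path():
    rng = np.random.default_rng(7)
    p = rng.uniform(0.01, 0.99, size=(5, 5))
    y = (rng.random((5, 5)) < 0.4).astype(float)
    assert float(dice_loss(Tensor(p), Tensor(y), 1e-6).data) == pytest.approx(
        dice_loss(p, y, 1e-6), rel=1e-12)
    assert float(focal_loss(Tensor(p), Tensor(y)).data) == pytest.approx(
        focal_loss(p, y), rel=1e-12)
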