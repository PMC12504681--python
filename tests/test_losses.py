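"""Closed-form oracles and property tests for the metrics and the LCFT loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vnetpp._autograd import Tensor
from vnetpp.losses import (
    LossConfig,
    PerClassCounts,
    TverskyParams,
    dice_coefficient,
    focal_tversky_loss,
    hard_confusion_counts,
    jaccard_index,
    jaccard_loss,
    lcft_loss_from_counts,
    lcft_total_loss,
    log_cosh_dice_loss,
    soft_confusion_counts,
    tversky_index,
)


def counts1(tp, fp, fn, tn=100.0):
    return PerClassCounts(tp=[tp], fp=[fp], fn=[fn], tn=[tn], n_classes=1)


def scalar(x):
    return float(np.asarray(x).reshape(-1)[0])


def brute_force_counts(pred_onehot, truth_onehot):
    """Independent per-pixel counting loop (integer masks only)."""
    h, w, c = pred_onehot.shape
    tp = np.zeros(c)
    fp = np.zeros(c)
    fn = np.zeros(c)
    tn = np.zeros(c)
    for i in range(h):
        for j in range(w):
            for k in range(c):
                p, g = int(pred_onehot[i, j, k]), int(truth_onehot[i, j, k])
                if p and g:
                    tp[k] += 1
                elif p and not g:
                    fp[k] += 1
                elif not p and g:
                    fn[k] += 1
                else:
                    tn[k] += 1
    return tp, fp, fn, tn


class TestSoftConfusionCounts:
    def test_identity_case(self):
        mask = np.zeros((4, 4), dtype=int)
        mask.flat[:5] = 1
        truth = np.eye(2)[mask]
        c = soft_confusion_counts(truth, truth)
        assert c.tp[1] == 5 and c.fp[1] == 0 and c.fn[1] == 0
        assert c.tn[1] == 11

    def test_complement_case(self):
        mask = np.zeros((4, 4), dtype=int)
        mask.flat[:6] = 1
        truth = np.eye(2)[mask]
        probs = 1.0 - truth
        c = soft_confusion_counts(probs, truth)
        np.testing.assert_array_equal(c.tp, [0, 0])
        assert c.fp[0] == 6 and c.fn[0] == 10
        assert c.fp[1] == 10 and c.fn[1] == 6

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_loop(self, seed):
        rng = np.random.default_rng(seed)
        pred = np.eye(2)[(rng.random((16, 16)) > 0.5).astype(int)]
        truth = np.eye(2)[(rng.random((16, 16)) > 0.5).astype(int)]
        c = soft_confusion_counts(pred, truth)
        tp, fp, fn, tn = brute_force_counts(pred, truth)
        np.testing.assert_array_equal(c.tp, tp)
        np.testing.assert_array_equal(c.fp, fp)
        np.testing.assert_array_equal(c.fn, fn)
        np.testing.assert_array_equal(c.tn, tn)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            soft_confusion_counts(np.zeros((2, 2, 2)), np.zeros((3, 3, 2)))

    def test_probs_out_of_range_rejected(self):
        truth = np.eye(2)[np.zeros((2, 2), dtype=int)]
        with pytest.raises(ValueError, match="outside"):
            soft_confusion_counts(truth * 1.5 - 0.25, truth)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_conservation_invariants(self, seed):
        rng = np.random.default_rng(seed)
        logits = rng.normal(size=(5, 5, 3))
        probs = np.exp(logits) / np.exp(logits).sum(-1, keepdims=True)
        truth = np.eye(3)[rng.integers(0, 3, size=(5, 5))]
        c = soft_confusion_counts(probs, truth)
        np.testing.assert_allclose(c.tp + c.fn, truth.sum(axis=(0, 1)), atol=1e-9)
        np.testing.assert_allclose(c.total_pixels, 25.0, atol=1e-9)
        assert (c.tp >= 0).all() and (c.fp >= 0).all()
        assert (c.fn >= 0).all() and (c.tn >= -1e-9).all()


class TestMetricOracles:
    def test_dice_perfect(self):
        np.testing.assert_allclose(dice_coefficient(counts1(5, 0, 0), 0.0), 1.0)

    def test_dice_arithmetic(self):
        np.testing.assert_allclose(dice_coefficient(counts1(3, 1, 2), 0.0), 6 / 9)

    def test_dice_empty_vs_empty_is_perfect(self):
        np.testing.assert_allclose(dice_coefficient(counts1(0, 0, 0), 1e-6), 1.0)

    def test_jaccard_arithmetic(self):
        np.testing.assert_allclose(jaccard_index(counts1(3, 1, 2), 0.0), 0.5)

    def test_jaccard_perfect(self):
        np.testing.assert_allclose(jaccard_index(counts1(7, 0, 0), 0.0), 1.0)

    def test_jaccard_disjoint(self):
        np.testing.assert_allclose(jaccard_index(counts1(0, 1, 1), 0.0), 0.0)

    def test_tversky_half_half_is_dice(self):
        c = counts1(3, 1, 2)
        np.testing.assert_allclose(
            tversky_index(c, TverskyParams(0.5, 0.5), 0.0), 2 / 3, atol=1e-12
        )

    def test_tversky_one_one_is_jaccard(self):
        c = counts1(3, 1, 2)
        np.testing.assert_allclose(
            tversky_index(c, TverskyParams(1.0, 1.0), 0.0), 0.5, atol=1e-12
        )

    def test_tversky_asymmetric(self):
        c = counts1(3, 1, 2)
        np.testing.assert_allclose(
            tversky_index(c, TverskyParams(0.7, 0.3), 0.0), 3 / 4.7, atol=1e-12
        )


class TestLossComponents:
    def test_log_cosh_dice_zero_at_perfect(self):
        np.testing.assert_allclose(log_cosh_dice_loss(counts1(5, 0, 0), 0.0), 0.0)

    def test_log_cosh_dice_disjoint(self):
        np.testing.assert_allclose(
            log_cosh_dice_loss(counts1(0, 3, 3), 0.0), np.log(np.cosh(1.0)), atol=1e-9
        )
        assert abs(scalar(log_cosh_dice_loss(counts1(0, 3, 3), 0.0)) - 0.43378) < 1e-5

    def test_log_cosh_dice_third(self):
        val = scalar(log_cosh_dice_loss(counts1(3, 1, 2), 0.0))
        np.testing.assert_allclose(val, np.log(np.cosh(1 / 3)), atol=1e-12)
        assert abs(val - 0.05456) < 1e-5

    def test_focal_tversky_zero_and_unit(self):
        np.testing.assert_allclose(
            focal_tversky_loss(counts1(5, 0, 0), TverskyParams(0.7, 0.3), 0.75, 0.0), 0.0
        )
        np.testing.assert_allclose(
            focal_tversky_loss(counts1(0, 2, 2), TverskyParams(0.7, 0.3), 0.75, 0.0), 1.0
        )

    def test_focal_tversky_arithmetic(self):
        val = scalar(focal_tversky_loss(counts1(3, 1, 2), TverskyParams(0.7, 0.3), 0.75, 0.0))
        np.testing.assert_allclose(val, (1 - 3 / 4.7) ** 0.75, atol=1e-12)
        assert abs(val - 0.4664) < 1e-4

    def test_focal_gamma_one_is_tversky_loss(self):
        c = counts1(3, 1, 2)
        np.testing.assert_allclose(
            focal_tversky_loss(c, TverskyParams(0.7, 0.3), 1.0, 0.0),
            1.0 - tversky_index(c, TverskyParams(0.7, 0.3), 0.0),
            atol=1e-12,
        )

    def test_jaccard_loss_cases(self):
        np.testing.assert_allclose(jaccard_loss(counts1(5, 0, 0), 0.0), 0.0)
        np.testing.assert_allclose(jaccard_loss(counts1(0, 2, 2), 0.0), 1.0)
        np.testing.assert_allclose(jaccard_loss(counts1(3, 1, 2), 0.0), 0.5)


class TestTotalLoss:
    def test_perfect_prediction_zero(self):
        mask = np.zeros((6, 6), dtype=int)
        mask[2:4, 2:4] = 1
        truth = np.eye(2)[mask]
        assert float(lcft_total_loss(truth, truth)) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_masks_closed_form(self):
        mask = np.zeros((4, 4), dtype=int)
        mask.flat[:6] = 1
        truth = np.eye(2)[mask]
        val = float(lcft_total_loss(1.0 - truth, truth))
        expected = 0.6 * np.log(np.cosh(1.0)) + 0.2 * 1.0 + 0.2 * 1.0
        assert val == pytest.approx(expected, abs=1e-6)
        assert val == pytest.approx(0.66027, abs=1e-5)

    def test_counts_composition_closed_form(self):
        cfg = LossConfig(smooth=0.0)
        val = float(lcft_loss_from_counts(counts1(3, 1, 2), cfg))
        assert val == pytest.approx(0.22602, abs=1e-5)
        expected = (
            0.6 * np.log(np.cosh(1 / 3))
            + 0.2 * (1 - 3 / 4.7) ** 0.75
            + 0.2 * 0.5
        )
        assert val == pytest.approx(expected, abs=1e-12)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            LossConfig(w_lc=0.5, w_ft=0.2, w_j=0.2)

    def test_loss_in_unit_interval_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            logits = rng.normal(size=(8, 8, 4))
            probs = np.exp(logits) / np.exp(logits).sum(-1, keepdims=True)
            truth = np.eye(4)[rng.integers(0, 4, size=(8, 8))]
            val = float(lcft_total_loss(probs, truth))
            assert 0.0 <= val <= 1.0

    def test_differentiable_with_finite_nonzero_gradient(self):
        rng = np.random.default_rng(2)
        logits = rng.normal(size=(6, 6, 3))
        probs = np.exp(logits) / np.exp(logits).sum(-1, keepdims=True)
        truth = np.eye(3)[rng.integers(0, 3, size=(6, 6))]
        p = Tensor(probs, requires_grad=True)
        loss = lcft_total_loss(p, Tensor(truth))
        loss.backward()
        assert np.isfinite(p.grad).all()
        assert np.abs(p.grad).max() > 0

    def test_macro_foreground_aggregation(self):
        cfg = LossConfig(smooth=0.0, class_aggregation="macro_foreground")
        c2 = PerClassCounts(tp=[10, 3], fp=[2, 1], fn=[1, 2], tn=[3, 10], n_classes=2)
        val = float(lcft_loss_from_counts(c2, cfg))
        assert val == pytest.approx(0.22602, abs=1e-5)

    def test_dice_kind_loss(self):
        cfg = LossConfig(smooth=0.0, kind="dice")
        val = float(lcft_loss_from_counts(counts1(3, 1, 2), cfg))
        assert val == pytest.approx(1 / 3, abs=1e-12)


class TestProperties:
    def test_reduction_identities_on_random_tuples(self):
        rng = np.random.default_rng(11)
        tp, fp, fn = rng.uniform(0, 50, size=(3, 1000))
        # one wide counts object vectorizes the 1000 random tuples
        c = PerClassCounts(tp=tp, fp=fp, fn=fn, tn=np.zeros(1000), n_classes=1000)
        np.testing.assert_allclose(
            tversky_index(c, TverskyParams(0.5, 0.5), 0.0),
            dice_coefficient(c, 0.0),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            tversky_index(c, TverskyParams(1.0, 1.0), 0.0),
            jaccard_index(c, 0.0),
            atol=1e-12,
        )

    @given(
        st.floats(0, 100),
        st.floats(0, 100),
        st.floats(0, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_jaccard_le_dice_le_one(self, tp, fp, fn):
        c = counts1(tp, fp, fn)
        j = scalar(jaccard_index(c))
        d = scalar(dice_coefficient(c))
        assert j <= d + 1e-12
        assert d <= 1.0 + 1e-12

    def test_tversky_strictly_decreasing_in_fn(self):
        params = TverskyParams(0.7, 0.3)
        vals = [scalar(tversky_index(counts1(5, 2, fn), params, 0.0)) for fn in (1, 2, 3)]
        assert vals[0] > vals[1] > vals[2]

    def test_fn_penalized_more_than_fp(self):
        cfg = LossConfig(smooth=0.0)
        base = float(lcft_loss_from_counts(counts1(5, 2, 2), cfg))
        plus_fn = float(lcft_loss_from_counts(counts1(5, 2, 3), cfg))
        plus_fp = float(lcft_loss_from_counts(counts1(5, 3, 2), cfg))
        assert plus_fn - base > plus_fp - base > 0

    def test_soft_equals_hard_on_hard_masks(self):
        rng = np.random.default_rng(3)
        mask_p = (rng.random((16, 16)) > 0.5).astype(int)
        mask_t = (rng.random((16, 16)) > 0.5).astype(int)
        soft = soft_confusion_counts(np.eye(2)[mask_p], np.eye(2)[mask_t])
        hard = hard_confusion_counts(mask_p, mask_t, 2)
        for attr in ("tp", "fp", "fn", "tn"):
            np.testing.assert_array_equal(getattr(soft, attr), getattr(hard, attr))


class TestValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            counts1(-1, 0, 0)

    def test_tversky_params_nonnegative(self):
        with pytest.raises(ValueError):
            TverskyParams(-0.1, 0.3)

    def test_focal_gamma_positive(self):
        with pytest.raises(ValueError):
            LossConfig(focal_gamma=0.0)
        with pytest.raises(ValueError):
            focal_tversky_loss(counts1(1, 1, 1), focal_gamma=-1.0)

    def test_bad_aggregation_rejected(self):
        with pytest.raises(ValueError, match="class_aggregation"):
            LossConfig(class_aggregation="micro")
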