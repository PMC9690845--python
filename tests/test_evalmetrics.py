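"""Metric correctness against brute-force oracles, plus the algebraic
identities linking DSC/JI and AER/FPR/TPR."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from estan.evalmetrics import (area_metrics, boundary_distances,
                               boundary_pixels, dice_loss, evaluate_sample)

from conftest import random_blob, random_mask


def confusion_oracle(pred, gt):
    """Per-pixel python-loop confusion counting."""
    tp = fp = fn = 0
    for p, g in zip(np.asarray(pred).ravel().tolist(),
                    np.asarray(gt).ravel().tolist()):
        p, g = bool(p), bool(g)
        tp += p and g
        fp += p and not g
        fn += (not p) and g
    return tp, fp, fn


def boundary_oracle(mask):
    """Direct 4-neighbour scan; border counts as outside."""
    m = np.asarray(mask).astype(bool)
    h, w = m.shape
    out = np.zeros_like(m)
    for i in range(h):
        for j in range(w):
            if not m[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not m[ni, nj]:
                    out[i, j] = True
                    break
    return out


def hd_mae_oracle(pred, gt):
    a = np.argwhere(boundary_oracle(pred)).astype(float)
    g = np.argwhere(boundary_oracle(gt)).astype(float)
    d = cdist(a, g)
    d_ag = d.min(axis=1)
    d_ga = d.min(axis=0)
    hd = max(d_ag.max(), d_ga.max())
    mae = (d_ag.sum() + d_ga.sum()) / (len(a) + len(g))
    return hd, mae


class TestDiceLoss:
    def test_perfect_match_near_zero(self):
        t = np.zeros((10, 10))
        t[2:6, 2:6] = 1
        n = t.sum()
        for eps in (1.0, 0.1, 0.01):
            assert dice_loss(t, t, eps=eps) == pytest.approx(0.0, abs=eps / (2 * n))

    def test_loss_bound_shrinks_with_eps(self):
        """For pred = target the loss is bounded by eps/(2n+eps), which
        vanishes monotonically as eps -> 0 (here the bound is tight at 0)."""
        t = np.zeros((8, 8))
        t[1:4, 1:4] = 1
        n = t.sum()
        losses = [dice_loss(t, t, eps=e) for e in (1.0, 0.5, 0.1, 0.01)]
        bounds = [e / (2 * n + e) for e in (1.0, 0.5, 0.1, 0.01)]
        assert all(l <= b for l, b in zip(losses, bounds))
        assert all(a >= b for a, b in zip(losses, losses[1:]))
        assert losses[-1] < 1e-3

    def test_disjoint_prediction_tends_to_one(self):
        t = np.zeros((10, 10))
        t[:, :5] = 1
        assert dice_loss(1 - t, t, eps=1e-9) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_half_probability_closed_form(self):
        big_n, n = 400, 30
        t = np.zeros(big_n)
        t[:n] = 1
        eps = 1.0
        expected = 1 - (n + eps) / (big_n / 2 + n + eps)
        assert dice_loss(np.full(big_n, 0.5), t, eps=eps) == pytest.approx(expected)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice_loss(np.zeros((3, 3)), np.zeros((4, 4)))


class TestAreaMetrics:
    def test_identity_prediction(self):
        gt = random_mask(np.random.default_rng(0))
        assert area_metrics(gt, gt) == (1.0, 0.0, 1.0, 1.0, 0.0)

    def test_two_square_configuration(self):
        gt = np.zeros((6, 6), dtype=np.uint8)
        pred = np.zeros((6, 6), dtype=np.uint8)
        gt[2:4, 2:4] = 1          # 2x2 square
        pred[2:4, 3:5] = 1        # overlaps in a 2x1 strip
        tpr, fpr, ji, dsc, aer = area_metrics(pred, gt)
        assert (tpr, fpr, dsc, aer) == (0.5, 0.5, 0.5, 1.0)
        assert ji == pytest.approx(1 / 3)

    def test_fpr_exceeds_one_iff_fp_outgrows_gt(self):
        gt = np.zeros((10, 10), dtype=np.uint8)
        gt[0, 0] = 1
        pred = np.ones((10, 10), dtype=np.uint8)
        tpr, fpr, *_ = area_metrics(pred, gt)
        assert fpr == 99.0 and fpr > 1

    def test_empty_gt_raises(self):
        with pytest.raises(ValueError, match="empty ground-truth"):
            area_metrics(np.ones((4, 4)), np.zeros((4, 4)))

    def test_matches_confusion_oracle_and_identities(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            gt = random_mask(rng)
            pred = random_mask(rng, nonempty=False)
            tp, fp, fn = confusion_oracle(pred, gt)
            tpr, fpr, ji, dsc, aer = area_metrics(pred, gt)
            n_gt = gt.sum()
            assert tpr == pytest.approx(tp / n_gt)
            assert fpr == pytest.approx(fp / n_gt)
            assert ji == pytest.approx(tp / (tp + fp + fn) if tp + fp + fn else 1.0)
            assert dsc == pytest.approx(2 * ji / (1 + ji), abs=1e-9)
            assert aer == pytest.approx(fpr + (1 - tpr), abs=1e-9)


class TestBoundary:
    def test_single_pixel_is_its_own_boundary(self):
        m = np.zeros((5, 5))
        m[2, 3] = 1
        b = boundary_pixels(m)
        assert b.sum() == 1 and b[2, 3]

    def test_filled_square_perimeter(self):
        m = np.zeros((8, 8))
        m[2:6, 2:6] = 1
        b = boundary_pixels(m)
        assert b.sum() == 12 and not b[3:5, 3:5].any()

    def test_border_counts_as_outside(self):
        m = np.ones((4, 4))
        assert boundary_pixels(m).sum() == 12    # interior 2x2 excluded

    def test_matches_neighbor_scan_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = random_blob(rng, shape=(32, 32))
            np.testing.assert_array_equal(boundary_pixels(m), boundary_oracle(m))

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            boundary_pixels(np.zeros((3, 3)))


class TestBoundaryDistances:
    def test_identical_masks_zero(self):
        m = random_blob(np.random.default_rng(1), shape=(32, 32))
        assert boundary_distances(m, m) == (0.0, 0.0)

    def test_singletons_five_apart(self):
        a = np.zeros((10, 10))
        b = np.zeros((10, 10))
        a[4, 2] = 1
        b[4, 7] = 1
        assert boundary_distances(a, b) == (5.0, 5.0)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            a = random_blob(rng, shape=(32, 32))
            g = random_blob(rng, shape=(32, 32))
            hd, mae = boundary_distances(a, g)
            ohd, omae = hd_mae_oracle(a, g)
            assert hd == pytest.approx(ohd, abs=1e-9)
            assert mae == pytest.approx(omae, abs=1e-9)

    def test_symmetric_and_ordered(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = random_blob(rng, shape=(24, 24))
            g = random_blob(rng, shape=(24, 24))
            hd, mae = boundary_distances(a, g)
            assert (hd, mae) == boundary_distances(g, a)
            assert hd >= mae >= 0


class TestEvaluateSample:
    def test_exact_probability_map(self):
        gt = random_blob(np.random.default_rng(2), shape=(32, 32))
        r = evaluate_sample(gt.astype(float), gt, sample_id="x")
        assert r.dsc == 1.0 and r.hd == 0.0 and r.flags == ""

    def test_no_detection_flags_boundary_metrics(self):
        gt = random_blob(np.random.default_rng(4), shape=(32, 32))
        r = evaluate_sample(np.zeros_like(gt, dtype=float), gt)
        assert (r.tpr, r.fpr, r.ji, r.dsc, r.aer) == (0, 0, 0, 0, 1)
        assert np.isnan(r.hd) and np.isnan(r.mae) and r.flags == "empty_pred"

    def test_threshold_monotone_shrinkage(self):
        rng = np.random.default_rng(8)
        prob = rng.uniform(size=(32, 32))
        low = prob > 0.4
        high = prob > 0.6
        assert (high <= low).all()
        gt = random_blob(rng, shape=(32, 32))
        r_low = evaluate_sample(prob, gt, threshold=0.4)
        r_high = evaluate_sample(prob, gt, threshold=0.6)
        assert r_high.fpr <= r_low.fpr and r_high.tpr <= r_low.tpr

    def test_empty_gt_skipped_with_reason(self):
        with pytest.raises(ValueError, match="empty ground truth"):
            evaluate_sample(np.ones((4, 4)) * 0.9, np.zeros((4, 4)), sample_id="z")
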