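"""Weighted IoU loss and loss-weight maps against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from papillae.losses import (
    papillae_loss_weights,
    tongue_loss_weights,
    weighted_iou_loss,
    weighted_iou_loss_grad,
)

from conftest import flood_fill_count


def brute_force_loss(y, yhat, w):
    """Literal double-sum evaluation of the weighted IoU loss."""
    V, H = y.shape
    num = 0.0
    s_y = 0.0
    s_yw = 0.0
    for v in range(V):
        for h in range(H):
            num += y[v, h] * yhat[v, h]
            s_y += y[v, h]
            s_yw += yhat[v, h] * w[v, h]
    denom = s_y + s_yw - num
    return 0.0 if denom == 0 else 1.0 - num / denom


def brute_force_papillae_weights(mask, radius=15, boost=10.0):
    """Per-component minimum distances computed from explicit pixel lists."""
    mask = np.asarray(mask).astype(bool)
    comps = []
    seen = np.zeros_like(mask)
    for r0, c0 in zip(*np.nonzero(mask)):
        if seen[r0, c0]:
            continue
        stack = [(int(r0), int(c0))]
        seen[r0, c0] = True
        pix = []
        while stack:
            r, c = stack.pop()
            pix.append((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < mask.shape[0]
                        and 0 <= cc < mask.shape[1]
                        and mask[rr, cc]
                        and not seen[rr, cc]
                    ):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
        comps.append(np.array(pix, dtype=float))
    out = np.ones(mask.shape)
    if len(comps) < 2:
        return out
    coords = np.argwhere(np.ones(mask.shape, dtype=bool)).astype(float)
    near = np.zeros(len(coords))
    for pix in comps:
        near += cdist(coords, pix).min(axis=1) <= radius
    out[near.reshape(mask.shape) >= 2] = boost
    return out


class TestWeightedIoULoss:
    def test_perfect_overlap_is_zero(self):
        y = np.ones((2, 2))
        assert weighted_iou_loss(y, y, np.ones((2, 2))) == pytest.approx(0.0, abs=1e-7)

    def test_no_overlap_is_one(self):
        y = np.ones((2, 2))
        assert weighted_iou_loss(y, np.zeros((2, 2))) == pytest.approx(1.0, abs=1e-7)

    def test_hand_evaluated_half(self):
        y = np.array([[1, 0], [0, 0]], dtype=float)
        yhat = np.array([[1, 1], [0, 0]], dtype=float)
        # intersection 1, |y| = 1, |ŷ·w| = 2  ->  L = 1 - 1/(1+2-1) = 0.5
        assert weighted_iou_loss(y, yhat) == pytest.approx(0.5, abs=1e-7)

    def test_doubly_empty_is_zero(self):
        z = np.zeros((3, 3))
        assert weighted_iou_loss(z, z) == 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            weighted_iou_loss(np.ones((2, 2)), np.ones((2, 3)))

    def test_matches_brute_force_double_sum(self, rng):
        for _ in range(50):
            v, h = rng.integers(1, 17, size=2)
            y = (rng.random((v, h)) < 0.3).astype(float)
            yhat = rng.random((v, h))
            w = 1.0 + 9.0 * rng.random((v, h))
            assert weighted_iou_loss(y, yhat, w) == pytest.approx(
                brute_force_loss(y, yhat, w), abs=1e-10
            )

    def test_reduces_to_jaccard_distance(self, rng):
        """With w = 1 and binary predictions, L is the set Jaccard distance."""
        for _ in range(50):
            y = (rng.random((12, 12)) < 0.4)
            yhat = (rng.random((12, 12)) < 0.4)
            union = np.sum(y | yhat)
            expected = 0.0 if union == 0 else 1.0 - np.sum(y & yhat) / union
            assert weighted_iou_loss(y.astype(float), yhat.astype(float)) == pytest.approx(
                expected, abs=1e-6
            )

    def test_bounds_and_weight_monotonicity(self, rng):
        y = (rng.random((10, 10)) < 0.3).astype(float)
        yhat = rng.random((10, 10))
        w = np.ones((10, 10))
        base = weighted_iou_loss(y, yhat, w)
        assert 0.0 <= base <= 1.0
        # boosting weights on false-positive pixels never decreases the loss
        w_boost = w.copy()
        w_boost[(y == 0) & (yhat > 0.5)] = 10.0
        assert weighted_iou_loss(y, yhat, w_boost) >= base - 1e-12

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_bounds_and_oracle_property(self, seed):
        """For any mask/probability/weight triple: L in [0,1] and L equals
        the literal double-sum of the defining equation."""
        r = np.random.default_rng(seed)
        v, h = r.integers(1, 13, size=2)
        y = (r.random((v, h)) < r.uniform(0.0, 0.8)).astype(float)
        yhat = r.random((v, h))
        w = 1.0 + 9.0 * r.random((v, h))
        loss = weighted_iou_loss(y, yhat, w)
        assert 0.0 <= loss <= 1.0
        assert loss == pytest.approx(brute_force_loss(y, yhat, w), abs=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        y = (rng.random((5, 5)) < 0.4).astype(float)
        yhat = rng.random((5, 5)) * 0.8 + 0.1
        w = 1.0 + 4.0 * rng.random((5, 5))
        loss, grad = weighted_iou_loss_grad(y, yhat, w)
        eps = 1e-6
        for idx in [(0, 0), (2, 3), (4, 4)]:
            up = yhat.copy(); up[idx] += eps
            dn = yhat.copy(); dn[idx] -= eps
            fd = (weighted_iou_loss(y, up, w) - weighted_iou_loss(y, dn, w)) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestPapillaeLossWeights:
    def test_single_component_all_ones(self):
        mask = np.zeros((20, 20), bool)
        mask[5:8, 5:8] = True
        assert np.all(papillae_loss_weights(mask) == 1.0)

    def test_empty_mask_all_ones(self):
        assert np.all(papillae_loss_weights(np.zeros((10, 10), bool)) == 1.0)

    def test_two_points_boost_between(self):
        mask = np.zeros((9, 40), bool)
        mask[4, 5] = True
        mask[4, 25] = True  # 20 px apart on one row
        w = papillae_loss_weights(mask)
        mid = w[4, 10:21]
        assert np.all(mid == 10.0)  # within 15 px of both points
        assert w[4, 0] == 1.0 and w[4, 39] == 1.0
        np.testing.assert_array_equal(w, brute_force_papillae_weights(mask))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        v, h = rng.integers(8, 65, size=2)
        mask = np.zeros((v, h), bool)
        for _ in range(rng.integers(0, 6)):
            r, c = rng.integers(0, v), rng.integers(0, h)
            mask[max(0, r - 1): r + 2, max(0, c - 1): c + 2] = True
        np.testing.assert_array_equal(
            papillae_loss_weights(mask), brute_force_papillae_weights(mask)
        )

    def test_component_count_oracle_agrees(self, rng):
        from scipy import ndimage
        mask = rng.random((30, 30)) < 0.1
        labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
        assert n == flood_fill_count(mask)


class TestTongueLossWeights:
    def test_empty_and_full(self):
        assert np.all(tongue_loss_weights(np.zeros((5, 5), bool)) == 1.0)
        assert np.all(tongue_loss_weights(np.ones((5, 5), bool)) == 5.0)

    def test_exact_pixel_counts(self, rng):
        lip = np.zeros((100, 100), bool)
        flat = rng.choice(10000, size=1000, replace=False)
        lip[np.unravel_index(flat, lip.shape)] = True
        w = tongue_loss_weights(lip)
        assert int(np.sum(w == 5.0)) == 1000
        assert int(np.sum(w == 1.0)) == 9000
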