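import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thyrus.nn.losses import (
    combined_loss,
    dice_score,
    edge_weight_map,
    loss_and_grad_logits,
    softmax,
)


class TestDiceScore:
    def test_identical_masks(self):
        m = np.zeros((5, 5), bool)
        m[1:4, 1:4] = True
        assert dice_score(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dice_score(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((1, 4), bool)
        b = np.zeros((1, 4), bool)
        a[0, :2] = True
        b[0, 1:3] = True
        assert dice_score(a, b) == 0.5

    def test_both_empty_defined_as_one(self):
        assert dice_score(np.zeros((3, 3)), np.zeros((3, 3))) == 1.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_score(np.zeros((3, 3)), np.zeros((4, 4)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((6, 6)) > 0.5
        b = rng.random((6, 6)) > 0.5
        d = dice_score(a, b)
        assert d == dice_score(b, a)
        assert 0.0 <= d <= 1.0


class TestEdgeWeights:
    def test_empty_mask_all_ones(self):
        assert np.array_equal(edge_weight_map(np.zeros((8, 8))), np.ones((8, 8)))

    def test_zero_lambda_all_ones(self):
        m = np.zeros((8, 8))
        m[2:6, 2:6] = 1
        assert np.array_equal(edge_weight_map(m, lam=0.0), np.ones((8, 8)))

    def test_weighted_region_matches_brute_force_neighbourhood_scan(self):
        rng = np.random.default_rng(4)
        m = rng.random((12, 12)) > 0.6
        lam, r = 2.0, 2
        w = edge_weight_map(m, lam, r)
        # brute force: a pixel is "boundary-adjacent" if within Chebyshev
        # distance r of a pixel whose 3×3 neighbourhood mixes classes
        h, wdt = m.shape
        padded = np.pad(m, 1, mode="edge")

        def is_gradient(i, j):
            neigh = padded[i : i + 3, j : j + 3]
            return neigh.any() and not neigh.all()

        grad = np.array([[is_gradient(i, j) for j in range(wdt)] for i in range(h)])
        near = np.zeros_like(grad)
        for i in range(h):
            for j in range(wdt):
                if grad[i, j]:
                    near[max(0, i - r) : i + r + 1, max(0, j - r) : j + r + 1] = True
        expected = 1.0 + lam * near
        assert np.array_equal(w, expected)


class TestCombinedLoss:
    def test_one_hot_prediction_gives_near_zero_loss(self):
        t = np.zeros((1, 8, 8), np.float32)
        t[0, 2:6, 2:6] = 1
        probs = np.stack([1.0 - t, t], axis=-1)
        probs = np.clip(probs, 1e-7, 1 - 1e-7)
        assert combined_loss(probs, t) < 1e-5

    def test_uniform_prediction_ce_term_is_ln2(self):
        t = (np.random.default_rng(0).random((2, 8, 8)) > 0.5).astype(np.float32)
        probs = np.full((2, 8, 8, 2), 0.5)
        loss_ce_only = combined_loss(probs, t, loss_weights=(0.0, 1.0))
        assert loss_ce_only == pytest.approx(np.log(2.0), rel=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_literal_reference_implementation(self, seed):
        """Oracle: a direct two-line soft-Dice + weighted-CE computation."""
        rng = np.random.default_rng(seed)
        logits = rng.normal(size=(1, 8, 8, 2)).astype(np.float32)
        probs = softmax(logits).astype(np.float64)
        t = (rng.random((1, 8, 8)) > 0.5).astype(np.float64)
        w = 1.0 + 2.0 * (rng.random((1, 8, 8)) > 0.7)
        eps = 1e-6
        ref_dice = 1 - (2 * (probs[..., 1] * t).sum() + eps) / (probs[..., 1].sum() + t.sum() + eps)
        ref_ce = (w * -np.log(np.where(t > 0.5, probs[..., 1], probs[..., 0]))).sum() / w.sum()
        ref = 1.0 * ref_dice + 1.0 * ref_ce
        assert combined_loss(probs, t, w) == pytest.approx(ref, abs=1e-6)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        logits = rng.normal(size=(1, 6, 6, 2)).astype(np.float32)
        t = (rng.random((1, 6, 6)) > 0.5).astype(np.float32)
        w = np.stack([edge_weight_map(m) for m in t])
        _, g = loss_and_grad_logits(logits, t, w)
        eps = 1e-3
        for _ in range(10):
            i = tuple(rng.integers(0, s) for s in logits.shape)
            lp = logits.copy()
            lp[i] += eps
            lm = logits.copy()
            lm[i] -= eps
            fd = (combined_loss(softmax(lp), t, w) - combined_loss(softmax(lm), t, w)) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=0.02, abs=1e-5)

    def test_loss_nonnegative(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(1, 8, 8, 2)).astype(np.float32)
        t = (rng.random((1, 8, 8)) > 0.5).astype(np.float32)
        assert combined_loss(softmax(logits), t) >= 0.0
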