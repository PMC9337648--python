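"""Combined Dice + cross-entropy loss, edge weight maps, and the Dice score.

Probability/logit tensors are channels-last, (N, H, W, n_classes), matching
the layer zoo; class 1 is the thyroid foreground.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

EPS = 1e-6

__all__ = ["softmax", "dice_score", "edge_weight_map", "combined_loss", "loss_and_grad_logits"]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def dice_score(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """2|A∩B|/(|A|+|B|); defined as 1.0 when both masks are empty."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def edge_weight_map(mask: np.ndarray, lam: float = 2.0, radius: int = 2) -> np.ndarray:
    """Per-pixel loss weights emphasising the mask contour.

    Weight is 1 + lam on pixels within `radius` of the boundary (morphological
    gradient of the mask dilated `radius` times with a 3×3 structure), 1
    elsewhere.  An empty (or full) mask has no boundary, hence all ones.
    """
    m = np.asarray(mask).astype(bool)
    if lam == 0.0:
        return np.ones(m.shape, dtype=np.float32)
    struct = np.ones((3, 3), dtype=bool)
    grad = ndimage.binary_dilation(m, struct) & ~ndimage.binary_erosion(m, struct, border_value=1)
    if radius > 0 and grad.any():
        grad = ndimage.binary_dilation(grad, struct, iterations=radius)
    return (1.0 + lam * grad).astype(np.float32)


def _soft_dice(p_fg: np.ndarray, target: np.ndarray) -> float:
    inter = float((p_fg * target).sum())
    denom = float(p_fg.sum() + target.sum())
    return (2.0 * inter + EPS) / (denom + EPS)


def combined_loss(
    probs: np.ndarray,
    target_mask: np.ndarray,
    weights: np.ndarray | None = None,
    loss_weights: tuple[float, float] = (1.0, 1.0),
) -> float:
    """w_dice·(1 − soft-Dice over foreground) + w_ce·(weighted mean cross-entropy).

    probs: (N,H,W,2) per-pixel class probabilities; target_mask: (N,H,W) binary.
    """
    probs = np.asarray(probs, dtype=np.float64)
    t = np.asarray(target_mask).astype(np.float64)
    if probs.shape[:3] != t.shape:
        raise ValueError("probs/target shape mismatch")
    w_dice, w_ce = loss_weights
    p_fg = probs[..., 1]
    dice_term = 1.0 - _soft_dice(p_fg, t)
    p_true = np.where(t > 0.5, p_fg, probs[..., 0])
    nll = -np.log(np.clip(p_true, 1e-12, None))
    if weights is None:
        ce_term = float(nll.mean())
    else:
        w = np.asarray(weights, dtype=np.float64)
        ce_term = float((w * nll).sum() / w.sum())
    return w_dice * dice_term + w_ce * ce_term


def loss_and_grad_logits(
    logits: np.ndarray,
    target_mask: np.ndarray,
    weights: np.ndarray | None = None,
    loss_weights: tuple[float, float] = (1.0, 1.0),
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the logits.

    Matches ``combined_loss(softmax(logits), ...)`` and backpropagates both the
    soft-Dice and the weighted cross-entropy terms through the softmax.
    """
    probs = softmax(logits)
    t = np.asarray(target_mask).astype(np.float32)
    w_dice, w_ce = loss_weights
    loss = combined_loss(probs, t, weights, loss_weights)

    n, h, w_, _ = probs.shape
    p_fg = probs[..., 1]
    # cross-entropy: d/dlogits = wgt·(p − onehot)/Σwgt
    onehot = np.stack([1.0 - t, t], axis=-1)
    if weights is None:
        wgt = np.full((n, h, w_), 1.0 / (n * h * w_), dtype=np.float32)
    else:
        wgt = np.asarray(weights, dtype=np.float32)
        wgt = wgt / wgt.sum()
    dlogits = w_ce * wgt[..., None] * (probs - onehot)
    # soft-Dice: dL/dp_fg, then through softmax (upstream only on the fg channel)
    inter = float((p_fg * t).sum())
    denom = float(p_fg.sum() + t.sum())
    # d(1−D)/dp_i = −(2 t_i (denom+EPS) − (2 inter+EPS)) / (denom+EPS)^2
    g_p = -(2.0 * t * (denom + EPS) - (2.0 * inter + EPS)) / (denom + EPS) ** 2
    g_p = (w_dice * g_p).astype(np.float32)
    dlogits[..., 1] += g_p * p_fg * (1.0 - p_fg)
    dlogits[..., 0] += -g_p * p_fg * probs[..., 0]
    return loss, dlogits.astype(np.float32)
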