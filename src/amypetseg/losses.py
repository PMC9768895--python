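"""Training objectives.

The segmentation objective is the soft-IoU (Jaccard) loss

    L = 1 - sum(p*g) / (sum(p) + sum(g) - sum(p*g))

where ``p`` are foreground softmax probabilities and ``g`` the binary
gold-standard mask.  The soft (probabilistic) intersection is used during
training; evaluation binarizes first, where ``1 - iou_loss`` coincides
exactly with the IoU metric.  Cross-entropy is provided for the slice-level
pathological-state classification head.

All functions are plain NumPy; :func:`iou_loss_grad` supplies the analytic
gradient backpropagated through the network.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "softmax",
    "iou_loss",
    "iou_loss_grad",
    "cross_entropy",
    "dice_loss",
    "total_loss",
]

_EPS = 1e-12


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stabilized softmax along ``axis``.

    Shift-invariant: adding any constant to all logits leaves the output
    unchanged (the max is subtracted before exponentiation).
    """
    z = np.asarray(logits, dtype=float)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _check_pair(p: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    g = np.asarray(g, dtype=float)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if not np.all(np.isin(np.unique(g), (0.0, 1.0))):
        raise ValueError("gold-standard mask must be binary")
    return p, g


def iou_loss(p: np.ndarray, g: np.ndarray) -> float:
    """Soft-IoU loss, in [0, 1]; 0 iff p equals g on the support union.

    Empty prediction vs empty mask is defined as loss 0 with a warning.
    """
    p, g = _check_pair(p, g)
    inter = float((p * g).sum())
    union = float(p.sum() + g.sum() - inter)
    if union == 0:
        warnings.warn("soft-IoU of two empty maps defined as loss 0", stacklevel=2)
        return 0.0
    return 1.0 - inter / union


def iou_loss_grad(p: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Analytic gradient of :func:`iou_loss` with respect to ``p``.

    With I = sum(p*g) and U = sum(p) + sum(g) - I,
    dL/dp_i = -(g_i * U - I * (1 - g_i)) / U^2.
    """
    p, g = _check_pair(p, g)
    inter = (p * g).sum()
    union = p.sum() + g.sum() - inter
    if union == 0:
        return np.zeros_like(p)
    return -(g * union - inter * (1.0 - g)) / union**2


def cross_entropy(t: np.ndarray, y: np.ndarray, eps: float = _EPS) -> float:
    """Cross-entropy -sum(t * log y) for a one-hot target.

    ``y`` is clamped below at ``eps`` so a zero probability on the true class
    yields a large finite loss rather than an infinity.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape:
        raise ValueError("target and prediction shapes differ")
    if not np.all(np.isin(np.unique(t), (0.0, 1.0))) or t.sum() != 1.0:
        raise ValueError("target must be one-hot")
    if y.min() < 0 or abs(y.sum() - 1.0) > 1e-6:
        raise ValueError("prediction must be a probability vector")
    return float(-(t * np.log(np.clip(y, eps, None))).sum())


def dice_loss(p: np.ndarray, g: np.ndarray) -> float:
    """Soft Dice loss 1 - 2·sum(pg)/(sum(p)+sum(g)); cross-check companion."""
    p, g = _check_pair(p, g)
    denom = float(p.sum() + g.sum())
    if denom == 0:
        return 0.0
    return 1.0 - 2.0 * float((p * g).sum()) / denom


def total_loss(
    p: np.ndarray,
    g: np.ndarray,
    class_target: np.ndarray | None = None,
    class_probs: np.ndarray | None = None,
    classification_weight: float = 0.0,
) -> float:
    """Combined objective: soft-IoU plus ``classification_weight`` x cross-entropy.

    The default weight 0 trains segmentation only; the classification head for
    slice-level positive/negative diagnosis is enabled by a positive weight.
    """
    loss = iou_loss(p, g)
    if classification_weight > 0:
        if class_target is None or class_probs is None:
            raise ValueError("classification head requires target and probabilities")
        loss += classification_weight * cross_entropy(class_target, class_probs)
    return loss
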