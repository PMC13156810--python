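"""Segmentation losses: binary cross-entropy + soft-Dice at 1:1 weighting,
with optional deep supervision over the decoder's resolution pyramid."""

from __future__ import annotations

import numpy as np

__all__ = ["sigmoid", "bce_with_logits", "soft_dice", "bce_dice_loss",
           "deep_supervision_loss", "downsample_target"]

_EPS = 1e-7


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy; returns (loss, dloss/dlogits)."""
    if logits.shape != target.shape:
        raise ValueError(f"shape mismatch: {logits.shape} vs {target.shape}")
    p = sigmoid(logits)
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    t = target.astype(np.float32)
    loss = float(-(t * np.log(pc) + (1 - t) * np.log(1 - pc)).mean())
    grad = (p - t) / p.size
    return loss, grad.astype(np.float32)


def soft_dice(probs: np.ndarray, target: np.ndarray, eps: float = 1e-5) -> float:
    """Soft Dice coefficient of probabilities against a binary target."""
    t = target.astype(np.float32)
    num = 2.0 * float((probs * t).sum()) + eps
    den = float(probs.sum() + t.sum()) + eps
    return num / den


def bce_dice_loss(
    logits: np.ndarray, target: np.ndarray, w_bce: float = 1.0, w_dice: float = 1.0
) -> tuple[float, np.ndarray]:
    """Combined loss ``w_bce * BCE + w_dice * (1 - softDice)``.

    Returns the scalar loss and its gradient with respect to the logits.
    """
    if logits.shape != target.shape:
        raise ValueError(f"shape mismatch: {logits.shape} vs {target.shape}")
    if w_bce < 0 or w_dice < 0:
        raise ValueError("loss weights must be positive")
    bce, dbce = bce_with_logits(logits, target)
    p = sigmoid(logits)
    t = target.astype(np.float32)
    eps = 1e-5
    num = 2.0 * float((p * t).sum()) + eps
    den = float(p.sum() + t.sum()) + eps
    dice = num / den
    # d(1 - dice)/dp = -(2 t den - num) / den^2 ; chain through the sigmoid
    ddice_dp = -(2.0 * t * den - num) / den**2
    ddice = ddice_dp * p * (1.0 - p)
    loss = w_bce * bce + w_dice * (1.0 - dice)
    grad = (w_bce * dbce + w_dice * ddice).astype(np.float32)
    return float(loss), grad


def downsample_target(target: np.ndarray, levels: int, ndim: int) -> list[np.ndarray]:
    """Block-maximum pyramid of a binary target (keeps thin vessels present)."""
    out = [target.astype(np.float32)]
    cur = out[0]
    for _ in range(levels - 1):
        shape: list[int] = list(cur.shape[:2])
        for s in cur.shape[2:]:
            shape += [s // 2, 2]
        axes = tuple(3 + 2 * i for i in range(ndim))
        cur = cur.reshape(shape).max(axis=axes)
        out.append(cur)
    return out


def deep_supervision_loss(
    logits_list: list[np.ndarray],
    target: np.ndarray,
    ndim: int,
    w_bce: float = 1.0,
    w_dice: float = 1.0,
) -> tuple[float, list[np.ndarray]]:
    """Sum of per-resolution combined losses.

    ``logits_list`` runs from full resolution downwards.  Per-level weights
    halve with depth and are normalized to sum to one.
    """
    L = len(logits_list)
    weights = np.array([0.5**i for i in range(L)])
    weights /= weights.sum()
    targets = downsample_target(target, L, ndim)
    total = 0.0
    grads = []
    for w, lg, tg in zip(weights, logits_list, targets):
        loss, g = bce_dice_loss(lg, tg, w_bce, w_dice)
        total += w * loss
        grads.append((w * g).astype(np.float32))
    return float(total), grads
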