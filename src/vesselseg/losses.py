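"""Composite training objective: soft Dice plus class-weighted cross-entropy.

Vessel pixels are a small minority of a fundus frame (a few percent inside
the FOV), so plain cross-entropy under-trains the vessel class.  The
objective here combines a soft Dice term, which measures overlap and is
insensitive to class prevalence, with a cross-entropy term whose positive
and negative branches are down-weighted by how well each class is already
being predicted: the positive weight is ``1 − TP/N_p`` and the negative
weight ``1 − TN/N_n``, where N_p/N_n count predicted-positive and
predicted-negative pixels at a 0.5 threshold and TP/TN count the correct
ones among them.  The two terms are mixed as ``dice + λ·ce`` with λ = 0.5.

Each function returns ``(value, gradient_wrt_p)`` so the training loop can
feed the gradient straight into the network's backward pass; the
cross-entropy weights are treated as constants (no gradient through the
thresholding).
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

EPS = 1e-7
DEFAULT_LAMBDA = 0.5

__all__ = ["EPS", "DEFAULT_LAMBDA", "dice_loss", "weighted_ce", "combined_loss", "dice_coefficient"]


def _check(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    return p, q


def dice_coefficient(pred: np.ndarray, gt: np.ndarray) -> float:
    """Hard Dice overlap 2|X∩Y|/(|X|+|Y|) between two binary masks."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    denom = pred.sum() + gt.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(pred, gt).sum() / denom


def dice_loss(p: np.ndarray, q: np.ndarray, eps: float = EPS) -> tuple[float, np.ndarray]:
    """Soft Dice loss 1 − 2Σpq / (Σp² + Σq² + ε) and its gradient in p."""
    p, q = _check(p, q)
    inter = float((p * q).sum())
    denom = float((p * p).sum() + (q * q).sum()) + eps
    value = 1.0 - 2.0 * inter / denom
    grad = -2.0 * q / denom + 4.0 * inter * p / denom**2
    return value, grad


def weighted_ce(p: np.ndarray, y: np.ndarray, eps: float = EPS) -> tuple[float, np.ndarray]:
    """Class-weighted binary cross-entropy, averaged over pixels.

    Weights derive from a hard 0.5 thresholding of ``p`` recomputed per
    call (per batch in training); a class with no predicted pixels gets
    weight 1 (the limit convention).
    """
    p, y = _check(p, y)
    n = p.size
    pc = np.clip(p, eps, 1.0 - eps)
    pred_pos = p > 0.5
    n_p = int(pred_pos.sum())
    n_n = n - n_p
    tp = int(np.logical_and(pred_pos, y > 0.5).sum())
    tn = int(np.logical_and(~pred_pos, y <= 0.5).sum())
    if n_p == 0 or n_n == 0:
        logger.debug("one-sided prediction (N_p=%d, N_n=%d); weight defaults to 1", n_p, n_n)
    w_pos = 1.0 - tp / n_p if n_p > 0 else 1.0
    w_neg = 1.0 - tn / n_n if n_n > 0 else 1.0
    value = -float((w_pos * y * np.log(pc) + w_neg * (1.0 - y) * np.log(1.0 - pc)).sum()) / n
    grad = -(w_pos * y / pc - w_neg * (1.0 - y) / (1.0 - pc)) / n
    # the clamp makes the loss flat outside [eps, 1-eps]
    grad = np.where((p < eps) | (p > 1.0 - eps), 0.0, grad)
    return value, grad


def combined_loss(p: np.ndarray, y: np.ndarray, lam: float = DEFAULT_LAMBDA,
                  eps: float = EPS) -> tuple[float, np.ndarray]:
    """Dice + λ·weighted cross-entropy."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    dv, dg = dice_loss(p, y, eps)
    cv, cg = weighted_ce(p, y, eps)
    return dv + lam * cv, dg + lam * cg
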