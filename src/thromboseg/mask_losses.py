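"""Classification and segmentation-mask losses.

The mask head of a two-stage detector predicts an m x m grid of foreground
probabilities per region of interest.  The baseline mask loss is the average
binary cross-entropy over that grid; here it is replaced by a weighted
binary focal loss

    L_WFL = lambda * L_pos + L_neg,
    L_pos = -zeta  * (1 - p)^gamma * log p,
    L_neg = -xi    * p^gamma       * log(1 - p),

where zeta is the binary ground-truth mask, xi = 1 - zeta its complement,
gamma the focal focusing exponent and lambda > 1 up-weights the (rare)
positive thrombus pixels.  With lambda = 1 and gamma = 0 the loss reduces
exactly to binary cross-entropy.  Classification keeps plain cross-entropy,
and the multi-task total is the unweighted sum L_cls + L_reg + L_mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FocalConfig",
    "bce_mask_loss",
    "focal_loss",
    "wfl_pos",
    "wfl_neg",
    "weighted_focal_mask_loss",
    "weighted_focal_mask_grad",
    "cross_entropy_cls",
    "total_loss",
    "mask_loss_batch",
]


@dataclass(frozen=True)
class FocalConfig:
    """Hyper-parameters of the focal-style mask losses.

    alpha_t weights the scalar focal loss; gamma is the focusing exponent
    (gamma = 0 recovers cross-entropy); lam up-weights the positive branch
    of the weighted binary focal loss; eps clamps probabilities away from
    {0, 1} before logarithms.  Reduction over the m x m grid is the mean
    (matching the 1/m^2 normalizer of the BCE mask loss) or the plain sum.
    """

    alpha_t: float = 0.25
    gamma: float = 2.0
    lam: float = 2.0
    eps: float = 1e-7
    reduction: str = "mean"

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.alpha_t < 0:
            raise ValueError("alpha_t must be >= 0")
        if not (0 < self.eps < 0.5):
            raise ValueError("eps must lie in (0, 0.5)")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")


def _clamp(p: np.ndarray, eps: float) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1] before clamping")
    return np.clip(p, eps, 1.0 - eps)


def _check_pair(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    gt = gt.astype(float)
    if not np.all((gt == 0.0) | (gt == 1.0)):
        raise ValueError("ground-truth mask entries must be exactly 0 or 1")
    return pred, gt


def _reduce(terms: np.ndarray, reduction: str) -> float:
    return float(terms.mean()) if reduction == "mean" else float(terms.sum())


def bce_mask_loss(pred: np.ndarray, gt: np.ndarray, eps: float = 1e-7) -> float:
    """Average binary cross-entropy over an m x m probability grid."""
    pred, gt = _check_pair(pred, gt)
    p = _clamp(pred, eps)
    terms = -(gt * np.log(p) + (1.0 - gt) * np.log(1.0 - p))
    return float(terms.mean())


def focal_loss(p_t, cfg: FocalConfig | None = None):
    """Scalar (or elementwise) focal loss -alpha_t (1 - p_t)^gamma log p_t.

    p_t is the predicted probability of the true class; easy examples
    (p_t near 1) are suppressed by the (1 - p_t)^gamma modulator.
    """
    cfg = cfg or FocalConfig()
    p = _clamp(p_t, cfg.eps)
    out = -cfg.alpha_t * (1.0 - p) ** cfg.gamma * np.log(p)
    return float(out) if np.isscalar(p_t) or np.ndim(p_t) == 0 else out


def wfl_pos(pred: np.ndarray, gt_pos: np.ndarray, cfg: FocalConfig | None = None) -> float:
    """Positive branch: masked focal term on foreground pixels only."""
    cfg = cfg or FocalConfig()
    pred, zeta = _check_pair(pred, gt_pos)
    p = _clamp(pred, cfg.eps)
    terms = -zeta * (1.0 - p) ** cfg.gamma * np.log(p)
    return _reduce(terms, cfg.reduction)


def wfl_neg(pred: np.ndarray, gt_neg: np.ndarray, cfg: FocalConfig | None = None) -> float:
    """Negative branch: mirrored focal term on background pixels only."""
    cfg = cfg or FocalConfig()
    pred, xi = _check_pair(pred, gt_neg)
    p = _clamp(pred, cfg.eps)
    terms = -xi * p**cfg.gamma * np.log(1.0 - p)
    return _reduce(terms, cfg.reduction)


def weighted_focal_mask_loss(
    pred: np.ndarray, gt: np.ndarray, cfg: FocalConfig | None = None
) -> float:
    """lam * wfl_pos + wfl_neg with the background mask derived as 1 - gt."""
    cfg = cfg or FocalConfig()
    pred, zeta = _check_pair(pred, gt)
    return cfg.lam * wfl_pos(pred, zeta, cfg) + wfl_neg(pred, 1.0 - zeta, cfg)


def weighted_focal_mask_grad(
    pred: np.ndarray, gt: np.ndarray, cfg: FocalConfig | None = None
) -> np.ndarray:
    """Elementwise d L_WFL / d p (at the clamped probabilities).

    Negative at positive pixels (the loss pushes p up) and positive at
    negative pixels (pushes p down).
    """
    cfg = cfg or FocalConfig()
    pred, zeta = _check_pair(pred, gt)
    p = _clamp(pred, cfg.eps)
    g = cfg.gamma
    if g > 0:
        pos = g * (1.0 - p) ** (g - 1.0) * np.log(p) - (1.0 - p) ** g / p
        neg = -g * p ** (g - 1.0) * np.log(1.0 - p) + p**g / (1.0 - p)
    else:
        pos = -1.0 / p
        neg = 1.0 / (1.0 - p)
    grad = cfg.lam * zeta * pos + (1.0 - zeta) * neg
    if cfg.reduction == "mean":
        grad = grad / pred.size
    return grad


def cross_entropy_cls(class_probs: np.ndarray, label: int) -> float:
    """-log p_label for a normalized class-probability vector."""
    probs = np.asarray(class_probs, dtype=float)
    if probs.ndim != 1:
        raise ValueError("class_probs must be a 1-D probability vector")
    if abs(float(probs.sum()) - 1.0) > 1e-6:
        raise ValueError(f"class probabilities must sum to 1, got {probs.sum()!r}")
    if not (isinstance(label, (int, np.integer)) and 0 <= label < probs.size):
        raise ValueError(f"invalid label index {label!r} for {probs.size} classes")
    return float(-np.log(np.clip(probs[label], 1e-300, 1.0)))


def total_loss(l_cls: float, l_reg: float, l_mask: float) -> float:
    """Multi-task total L = L_cls + L_reg + L_mask."""
    parts = (l_cls, l_reg, l_mask)
    if not all(math.isfinite(v) for v in parts):
        raise ValueError(f"loss components must be finite, got {parts!r}")
    return float(sum(parts))


def mask_loss_batch(
    preds: np.ndarray,
    gts: np.ndarray,
    roi_positive: np.ndarray,
    cfg: FocalConfig | None = None,
) -> float:
    """Weighted focal mask loss averaged over positive-sample ROIs only.

    The mask head is supervised only on ROIs matched to a foreground
    object; ``roi_positive`` flags those.  Returns 0 when no ROI is
    positive.
    """
    cfg = cfg or FocalConfig()
    preds = np.asarray(preds, dtype=float)
    gts = np.asarray(gts)
    flags = np.asarray(roi_positive, dtype=bool)
    if preds.shape != gts.shape or preds.ndim != 3:
        raise ValueError("preds and gts must both have shape (N, m, m)")
    if flags.shape != (preds.shape[0],):
        raise ValueError("roi_positive must have shape (N,)")
    values = [
        weighted_focal_mask_loss(p, g, cfg)
        for p, g, keep in zip(preds, gts, flags)
        if keep
    ]
    if not values:
        return 0.0
    return float(np.mean(values))
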