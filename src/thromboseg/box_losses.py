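"""Bounding-box geometry and regression losses for two-stage detectors.

Implements the IoU loss family (IoU, GIoU, DIoU, CIoU) alongside smooth-L1
coordinate regression, and their convex combination

    L_SCIoU = delta * L_smoothL1 + (1 - delta) * L_CIoU,

a drop-in bounding-box regression loss that keeps the per-coordinate
regression signal of smooth L1 while retaining CIoU's overlap, center
distance and aspect-ratio terms.  Every loss is provided with its exact
closed-form gradient with respect to the predicted box corners (subgradients
at the min/max kinks), so gradient-based box fitting needs no autodiff
framework.

Boxes are axis-aligned, in continuous 0-based pixel coordinates, corner
parameterized as (x_min, y_min, x_max, y_max).  Areas are products of side
lengths; there is no "+1 pixel" convention.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

__all__ = [
    "EPS",
    "BoundingBox",
    "CIoUComponents",
    "SCIoUConfig",
    "DegenerateBoxWarning",
    "iou",
    "enclosing_box",
    "smooth_l1",
    "smooth_l1_box",
    "iou_loss",
    "giou_loss",
    "diou_loss",
    "ciou_components",
    "ciou_loss",
    "sciou_loss",
    "loss_and_grad",
    "batch_loss",
    "LOSS_NAMES",
    "read_boxes_jsonl",
    "write_boxes_jsonl",
]

#: clamping constant for degenerate widths/heights and the c^2 divisor
EPS = 1e-7


class DegenerateBoxWarning(UserWarning):
    """Both boxes have zero area; the overlap fraction is defined as zero."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in continuous, 0-based pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        vals = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(isinstance(v, (int, float)) and math.isfinite(v) for v in vals):
            raise ValueError(f"box coordinates must be finite numbers, got {vals!r}")
        if self.x_max < self.x_min or self.y_max < self.y_min:
            raise ValueError(f"box must satisfy x_max >= x_min and y_max >= y_min, got {vals!r}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.x_min, self.y_min, self.x_max, self.y_max], dtype=float)

    @classmethod
    def from_array(cls, a: Iterable[float]) -> "BoundingBox":
        x1, y1, x2, y2 = (float(v) for v in a)
        return cls(x1, y1, x2, y2)


@dataclass(frozen=True)
class CIoUComponents:
    """The pieces that make up the CIoU penalty.

    ``rho_sq`` is the squared Euclidean distance between box centers,
    ``c_sq`` the squared diagonal of the smallest enclosing box, ``v`` the
    aspect-ratio concordance term and ``alpha`` its trade-off weight
    v / ((1 - IoU) + v), defined as 0 whenever v = 0.
    """

    iou: float
    rho_sq: float
    c_sq: float
    v: float
    alpha: float


@dataclass(frozen=True)
class SCIoUConfig:
    """Configuration for the combined smooth-L1 + CIoU loss.

    delta in [0, 1] weights the smooth-L1 term; 1 - delta weights CIoU.
    When ``normalize_coords`` is set (the default), x residuals are divided
    by ``image_width`` and y residuals by ``image_height`` before the
    smooth-L1 kernel, keeping the two mixed terms on comparable scales.
    The defaults correspond to the nominal 512x512 axial CTA slice.
    """

    delta: float = 0.2
    normalize_coords: bool = True
    image_width: float | None = 512.0
    image_height: float | None = 512.0

    def __post_init__(self) -> None:
        if not (isinstance(self.delta, (int, float)) and 0.0 <= self.delta <= 1.0):
            raise ValueError(f"delta must lie in [0, 1], got {self.delta!r}")

    def residual_scales(self) -> tuple[float, float]:
        if not self.normalize_coords:
            return 1.0, 1.0
        if self.image_width is None or self.image_height is None:
            raise ValueError(
                "normalize_coords=True requires image_width and image_height"
            )
        return float(self.image_width), float(self.image_height)


# ---------------------------------------------------------------------------
# internal value-and-gradient kernels (operate on length-4 float arrays)
# ---------------------------------------------------------------------------


def _intersection_parts(p: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Intersection area and its gradient w.r.t. the predicted corners."""
    ix1 = max(p[0], t[0])
    iy1 = max(p[1], t[1])
    ix2 = min(p[2], t[2])
    iy2 = min(p[3], t[3])
    iw = ix2 - ix1
    ih = iy2 - iy1
    grad = np.zeros(4)
    if iw > 0.0 and ih > 0.0:
        inter = iw * ih
        if p[0] > t[0]:
            grad[0] = -ih
        if p[1] > t[1]:
            grad[1] = -iw
        if p[2] < t[2]:
            grad[2] = ih
        if p[3] < t[3]:
            grad[3] = iw
        return inter, grad
    return 0.0, grad


def _union_parts(p: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray, float, np.ndarray]:
    inter, d_inter = _intersection_parts(p, t)
    w, h = p[2] - p[0], p[3] - p[1]
    area_p = w * h
    d_area = np.array([-h, -w, h, w])
    area_t = (t[2] - t[0]) * (t[3] - t[1])
    union = area_p + area_t - inter
    d_union = d_area - d_inter
    return inter, d_inter, union, d_union


def _iou_vg(p: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    inter, d_inter, union, d_union = _union_parts(p, t)
    if union <= 0.0:
        warnings.warn(
            "both boxes are degenerate (zero area); IoU defined as 0",
            DegenerateBoxWarning,
            stacklevel=3,
        )
        return 0.0, np.zeros(4)
    value = inter / union
    grad = (d_inter * union - inter * d_union) / union**2
    return value, grad


def _enclosing_parts(
    p: np.ndarray, t: np.ndarray
) -> tuple[float, float, float, np.ndarray, np.ndarray, np.ndarray]:
    """Enclosing-box side lengths ew/eh, area E and their gradients."""
    ew = max(p[2], t[2]) - min(p[0], t[0])
    eh = max(p[3], t[3]) - min(p[1], t[1])
    d_ew = np.zeros(4)
    d_eh = np.zeros(4)
    if p[0] < t[0]:
        d_ew[0] = -1.0
    if p[2] > t[2]:
        d_ew[2] = 1.0
    if p[1] < t[1]:
        d_eh[1] = -1.0
    if p[3] > t[3]:
        d_eh[3] = 1.0
    area = ew * eh
    d_area = eh * d_ew + ew * d_eh
    return ew, eh, area, d_ew, d_eh, d_area


def _giou_vg(p: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    inter, d_inter, union, d_union = _union_parts(p, t)
    _, _, e_area, _, _, d_e = _enclosing_parts(p, t)
    if e_area <= 0.0:
        raise ValueError("degenerate enclosing box: both boxes have zero extent")
    if np.array_equal(p, t):
        # global minimum; 0 is a valid subgradient at the IoU kink
        return 0.0, np.zeros(4)
    if union <= 0.0:
        iou_v, g_iou = 0.0, np.zeros(4)
    else:
        iou_v = inter / union
        g_iou = (d_inter * union - inter * d_union) / union**2
    # penalty = |E \ (B u Bgt)| / |E| = 1 - union / E
    penalty = (e_area - union) / e_area
    g_penalty = -(d_union * e_area - union * d_e) / e_area**2
    return 1.0 - iou_v + penalty, -g_iou + g_penalty


def _center_distance_parts(
    p: np.ndarray, t: np.ndarray
) -> tuple[float, np.ndarray, float, np.ndarray]:
    dx = (p[0] + p[2]) / 2.0 - (t[0] + t[2]) / 2.0
    dy = (p[1] + p[3]) / 2.0 - (t[1] + t[3]) / 2.0
    rho_sq = dx * dx + dy * dy
    d_rho = np.array([dx, dy, dx, dy])
    ew, eh, _, d_ew, d_eh, _ = _enclosing_parts(p, t)
    c_sq = ew * ew + eh * eh
    d_c = 2.0 * ew * d_ew + 2.0 * eh * d_eh
    return rho_sq, d_rho, c_sq, d_c


def _diou_vg(p: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    rho_sq, d_rho, c_sq, d_c = _center_distance_parts(p, t)
    if c_sq == 0.0:
        raise ValueError("both boxes collapse to a single coincident point (c^2 = 0)")
    if np.array_equal(p, t):
        # global minimum; 0 is a valid subgradient at the IoU kink
        return 0.0, np.zeros(4)
    iou_v, g_iou = _iou_vg(p, t)
    if c_sq < EPS:
        c_sq, d_c = EPS, np.zeros(4)
    penalty = rho_sq / c_sq
    g_penalty = (d_rho * c_sq - rho_sq * d_c) / c_sq**2
    return 1.0 - iou_v + penalty, -g_iou + g_penalty


def _aspect_parts(p: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Aspect-concordance term v = (4/pi^2)(atan(wt/ht) - atan(w/h))^2 and grad."""
    w_raw, h_raw = p[2] - p[0], p[3] - p[1]
    w, h = max(w_raw, EPS), max(h_raw, EPS)
    wt = max(t[2] - t[0], EPS)
    ht = max(t[3] - t[1], EPS)
    q = math.atan(wt / ht) - math.atan(w / h)
    v = (4.0 / math.pi**2) * q * q
    coeff = 8.0 / math.pi**2
    dv_dw = -coeff * q * h / (w * w + h * h)
    dv_dh = coeff * q * w / (w * w + h * h)
    grad = np.zeros(4)
    if w_raw > EPS:  # clamp inactive
        grad[0] = -dv_dw
        grad[2] = dv_dw
    if h_raw > EPS:
        grad[1] = -dv_dh
        grad[3] = dv_dh
    return v, grad


def _ciou_vg(p: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    diou_v, g_diou = _diou_vg(p, t)
    if np.array_equal(p, t):
        return diou_v, g_diou
    iou_v, g_iou = _iou_vg(p, t)
    v, d_v = _aspect_parts(p, t)
    if v == 0.0:
        return diou_v, g_diou
    denom = (1.0 - iou_v) + v  # > 0 whenever v > 0
    term = v * v / denom
    d_denom = -g_iou + d_v
    g_term = (2.0 * v * d_v * denom - v * v * d_denom) / denom**2
    return diou_v + term, g_diou + g_term


def _smooth_l1_scalar(x: float) -> float:
    ax = abs(x)
    return 0.5 * x * x if ax < 1.0 else ax - 0.5


def _smooth_l1_deriv(x: float) -> float:
    return x if abs(x) < 1.0 else math.copysign(1.0, x)


def _smooth_l1_box_vg(
    p: np.ndarray, t: np.ndarray, cfg: SCIoUConfig
) -> tuple[float, np.ndarray]:
    sx, sy = cfg.residual_scales()
    scales = np.array([sx, sy, sx, sy])
    residuals = (p - t) / scales
    value = float(sum(_smooth_l1_scalar(r) for r in residuals))
    grad = np.array([_smooth_l1_deriv(r) for r in residuals]) / scales
    return value, grad


def _sciou_vg(p: np.ndarray, t: np.ndarray, cfg: SCIoUConfig) -> tuple[float, np.ndarray]:
    l_s, g_s = _smooth_l1_box_vg(p, t, cfg)
    l_c, g_c = _ciou_vg(p, t)
    d = cfg.delta
    return d * l_s + (1.0 - d) * l_c, d * g_s + (1.0 - d) * g_c


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def iou(b1: BoundingBox, b2: BoundingBox) -> float:
    """Intersection-over-union overlap fraction in [0, 1].

    Defined as 0 (with a :class:`DegenerateBoxWarning`) when both boxes are
    degenerate, i.e. the union has zero area.
    """
    value, _ = _iou_vg(b1.as_array(), b2.as_array())
    return value


def enclosing_box(b1: BoundingBox, b2: BoundingBox) -> BoundingBox:
    """Smallest axis-aligned box covering both inputs."""
    return BoundingBox(
        min(b1.x_min, b2.x_min),
        min(b1.y_min, b2.y_min),
        max(b1.x_max, b2.x_max),
        max(b1.y_max, b2.y_max),
    )


def smooth_l1(x: float) -> float:
    """Huber-style kernel: 0.5 x^2 for |x| < 1, |x| - 0.5 otherwise."""
    if not math.isfinite(x):
        raise ValueError(f"smooth_l1 requires a finite residual, got {x!r}")
    return _smooth_l1_scalar(float(x))


def smooth_l1_box(
    pred: BoundingBox, target: BoundingBox, cfg: SCIoUConfig | None = None
) -> float:
    """Sum of the smooth-L1 kernel over the four corner residuals.

    With ``cfg.normalize_coords`` set, residuals are divided by the image
    width (x) and height (y) first.
    """
    cfg = cfg or SCIoUConfig()
    value, _ = _smooth_l1_box_vg(pred.as_array(), target.as_array(), cfg)
    return value


def iou_loss(pred: BoundingBox, target: BoundingBox) -> float:
    """Plain 1 - IoU; flat (zero gradient) for non-overlapping boxes."""
    return 1.0 - iou(pred, target)


def giou_loss(pred: BoundingBox, target: BoundingBox) -> float:
    """1 - IoU + |E \\ (B u Bgt)| / |E| with E the smallest enclosing box."""
    value, _ = _giou_vg(pred.as_array(), target.as_array())
    return value


def diou_loss(pred: BoundingBox, target: BoundingBox) -> float:
    """1 - IoU + rho^2(b, bgt) / c^2 (normalized center distance penalty)."""
    value, _ = _diou_vg(pred.as_array(), target.as_array())
    return value


def ciou_components(pred: BoundingBox, target: BoundingBox) -> CIoUComponents:
    """IoU, center distance, enclosing diagonal and aspect terms of CIoU."""
    p, t = pred.as_array(), target.as_array()
    iou_v, _ = _iou_vg(p, t)
    rho_sq, _, c_sq, _ = _center_distance_parts(p, t)
    v, _ = _aspect_parts(p, t)
    alpha = 0.0 if v == 0.0 else v / ((1.0 - iou_v) + v)
    return CIoUComponents(iou=iou_v, rho_sq=rho_sq, c_sq=c_sq, v=v, alpha=alpha)


def ciou_loss(pred: BoundingBox, target: BoundingBox) -> float:
    """DIoU plus the aspect-ratio penalty alpha * v."""
    value, _ = _ciou_vg(pred.as_array(), target.as_array())
    return value


def sciou_loss(
    pred: BoundingBox, target: BoundingBox, cfg: SCIoUConfig | None = None
) -> float:
    """delta * smooth_l1_box + (1 - delta) * ciou_loss."""
    cfg = cfg or SCIoUConfig()
    value, _ = _sciou_vg(pred.as_array(), target.as_array(), cfg)
    return value


def _iou_loss_vg(p: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    if np.array_equal(p, t) and (p[2] - p[0]) * (p[3] - p[1]) > 0:
        return 0.0, np.zeros(4)
    v, g = _iou_vg(p, t)
    return 1.0 - v, -g


_KERNELS: dict[str, Callable[..., tuple[float, np.ndarray]]] = {
    "smooth_l1": _smooth_l1_box_vg,
    "iou": _iou_loss_vg,
    "giou": _giou_vg,
    "diou": _diou_vg,
    "ciou": _ciou_vg,
    "sciou": _sciou_vg,
}

#: loss names accepted by :func:`loss_and_grad`, :func:`batch_loss` and the harness
LOSS_NAMES = tuple(_KERNELS)


def loss_and_grad(
    name: str,
    pred: BoundingBox | np.ndarray,
    target: BoundingBox | np.ndarray,
    cfg: SCIoUConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Loss value and its exact gradient w.r.t. the 4 predicted corners.

    ``name`` is one of ``smooth_l1, iou, giou, diou, ciou, sciou`` ("iou"
    means the loss 1 - IoU).  Boxes may be given as BoundingBox or as
    length-4 arrays (x_min, y_min, x_max, y_max).
    """
    if name not in _KERNELS:
        raise KeyError(f"unknown loss {name!r}; expected one of {LOSS_NAMES}")
    p = pred.as_array() if isinstance(pred, BoundingBox) else np.asarray(pred, float)
    t = target.as_array() if isinstance(target, BoundingBox) else np.asarray(target, float)
    if p.shape != (4,) or t.shape != (4,):
        raise ValueError("boxes must have exactly 4 coordinates")
    kernel = _KERNELS[name]
    if name in ("smooth_l1", "sciou"):
        return kernel(p, t, cfg or SCIoUConfig())
    return kernel(p, t)


def batch_loss(
    name: str,
    preds: np.ndarray,
    targets: np.ndarray,
    cfg: SCIoUConfig | None = None,
    reduction: str = "mean",
) -> float:
    """Reduce a loss over (N, 4) arrays of predicted/target boxes."""
    if reduction not in ("mean", "sum"):
        raise ValueError(f"reduction must be 'mean' or 'sum', got {reduction!r}")
    preds = np.asarray(preds, float)
    targets = np.asarray(targets, float)
    if preds.shape != targets.shape or preds.ndim != 2 or preds.shape[1] != 4:
        raise ValueError("preds and targets must both have shape (N, 4)")
    if preds.shape[0] == 0:
        return 0.0
    values = [loss_and_grad(name, p, t, cfg)[0] for p, t in zip(preds, targets)]
    total = float(sum(values))
    return total / len(values) if reduction == "mean" else total


# ---------------------------------------------------------------------------
# JSON-lines serialization: {slice, x_min, y_min, x_max, y_max, score}
# ---------------------------------------------------------------------------


def write_boxes_jsonl(path, records: Iterable[dict]) -> None:
    """Write box records as JSON lines.

    Each record carries ``slice``, the four corners and an optional
    ``score``; extra keys pass through unchanged.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_boxes_jsonl(path) -> list[dict]:
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            missing = {"slice", "x_min", "y_min", "x_max", "y_max"} - rec.keys()
            if missing:
                raise ValueError(f"{path}:{line_no} missing keys {sorted(missing)}")
            records.append(rec)
    return records
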