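"""Per-slice detection matching, precision/recall/F1 and the run filter.

A predicted box counts as a true positive when it overlaps a same-slice
ground-truth box with IoU >= 0.5 (the threshold is configurable).  Matching
is one-to-one and greedy in descending confidence, with ties broken by
higher IoU — the de-facto detection-benchmark convention.

Because thrombi extend over many adjacent axial slices while intensity
confusers fire on isolated ones, a detection is *confirmed* only when it
belongs to a run of at least ``min_run`` (default 8) consecutive positive
slices; detections outside confirmed runs are suppressed before
segmentation scoring.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .box_losses import BoundingBox, iou

__all__ = [
    "Detection",
    "GroundTruth",
    "MatchResult",
    "UndefinedMetricWarning",
    "match_detections",
    "precision",
    "recall",
    "f1_score",
    "consecutive_slice_filter",
    "confirmed_slice_mask",
]


class UndefinedMetricWarning(UserWarning):
    """A metric's denominator is zero; NaN is returned."""


@dataclass(frozen=True)
class Detection:
    """A scored predicted box on one axial slice."""

    slice_id: int
    box: BoundingBox
    score: float

    def __post_init__(self) -> None:
        if not (isinstance(self.slice_id, (int, np.integer)) and self.slice_id >= 0):
            raise ValueError(f"slice_id must be a non-negative integer, got {self.slice_id!r}")
        if not (math.isfinite(self.score) and 0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be a finite value in [0, 1], got {self.score!r}")


@dataclass(frozen=True)
class GroundTruth:
    """A ground-truth box on one axial slice."""

    slice_id: int
    box: BoundingBox

    def __post_init__(self) -> None:
        if not (isinstance(self.slice_id, (int, np.integer)) and self.slice_id >= 0):
            raise ValueError(f"slice_id must be a non-negative integer, got {self.slice_id!r}")


@dataclass(frozen=True)
class MatchResult:
    """TP/FP/FN tallies plus the matched (detection, ground-truth, IoU) pairs."""

    tp: int
    fp: int
    fn: int
    matches: tuple[tuple[int, int, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if len(self.matches) != self.tp:
            raise ValueError("number of matched pairs must equal tp")


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruth],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy one-to-one matching of detections to same-slice ground truth.

    Detections are visited in descending score order (stable on ties);
    each takes the unmatched ground-truth box of highest IoU, provided
    that IoU reaches the threshold.  Unmatched detections are false
    positives; unmatched ground-truth boxes are false negatives.
    """
    if not (0.0 < iou_threshold <= 1.0):
        raise ValueError(f"iou_threshold must lie in (0, 1], got {iou_threshold!r}")
    gt_by_slice: dict[int, list[int]] = {}
    for gi, gt in enumerate(gts):
        gt_by_slice.setdefault(gt.slice_id, []).append(gi)
    unmatched_gt = set(range(len(gts)))
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    matches: list[tuple[int, int, float]] = []
    for di in order:
        det = dets[di]
        best_gi, best_iou = -1, 0.0
        for gi in gt_by_slice.get(det.slice_id, ()):
            if gi not in unmatched_gt:
                continue
            ov = iou(det.box, gts[gi].box)
            if ov > best_iou:
                best_gi, best_iou = gi, ov
        if best_gi >= 0 and best_iou >= iou_threshold:
            unmatched_gt.discard(best_gi)
            matches.append((di, best_gi, best_iou))
    tp = len(matches)
    return MatchResult(
        tp=tp, fp=len(dets) - tp, fn=len(gts) - tp, matches=tuple(matches)
    )


def precision(m: MatchResult) -> float:
    """TP / (TP + FP); NaN with a warning when nothing was predicted."""
    denom = m.tp + m.fp
    if denom == 0:
        warnings.warn("precision undefined: no detections", UndefinedMetricWarning)
        return float("nan")
    return m.tp / denom


def recall(m: MatchResult) -> float:
    """TP / (TP + FN); NaN with a warning when there is no ground truth."""
    denom = m.tp + m.fn
    if denom == 0:
        warnings.warn("recall undefined: no ground truth", UndefinedMetricWarning)
        return float("nan")
    return m.tp / denom


def f1_score(p: float, r: float) -> float:
    """Harmonic mean 2pr / (p + r) of precision and recall."""
    for name, v in (("precision", p), ("recall", r)):
        if not (math.isfinite(v) and 0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
    if p == 0.0 and r == 0.0:
        warnings.warn("f1 undefined: precision and recall both zero", UndefinedMetricWarning)
        return float("nan")
    return 2.0 * p * r / (p + r)


def consecutive_slice_filter(
    per_slice_flags: Sequence[bool], min_run: int = 8
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive positive slices with length >= min_run.

    Returns half-open (start, stop) index ranges in increasing order.
    Slices outside every confirmed run should be suppressed before
    restoring the segmentation to 3D.
    """
    flags = np.asarray(per_slice_flags, dtype=bool)
    if flags.ndim != 1 or flags.size == 0:
        raise ValueError("per_slice_flags must be a non-empty 1-D sequence")
    if not (isinstance(min_run, (int, np.integer)) and min_run >= 1):
        raise ValueError(f"min_run must be an integer >= 1, got {min_run!r}")
    runs: list[tuple[int, int]] = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if i - start >= min_run:
                runs.append((start, i))
            start = None
    if start is not None and flags.size - start >= min_run:
        runs.append((start, int(flags.size)))
    return runs


def confirmed_slice_mask(per_slice_flags: Sequence[bool], min_run: int = 8) -> np.ndarray:
    """Boolean mask of slices belonging to a confirmed run."""
    flags = np.asarray(per_slice_flags, dtype=bool)
    out = np.zeros(flags.shape, dtype=bool)
    for start, stop in consecutive_slice_filter(flags, min_run):
        out[start:stop] = True
    return out
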