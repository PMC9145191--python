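"""Volumetric segmentation scoring on 3D volumes restored from 2D slices.

Per-slice binary masks are stacked back into a 3D voxel set per patient
and the predicted volume S is compared with the ground-truth volume T
using five region-overlap measures:

    total overlap  TO = |S n T| / |T|
    Dice           2 |S n T| / (|S| + |T|)
    Jaccard        |S n T| / |S u T|
    FN rate        |T - S| / |T|   (type II error; TO + FN = 1)
    FP rate        |S - T| / |S|   (type I error)

The foreground is treated as a single thrombus region (the task has
exactly two classes); no connected-component decomposition is applied.
Slice spacing is carried as metadata only — all scores are voxel-count
ratios and therefore spacing-invariant.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .detection_eval import UndefinedMetricWarning, confirmed_slice_mask

__all__ = [
    "LabeledVolume",
    "SegScores",
    "stack_slices",
    "total_overlap",
    "dice",
    "jaccard",
    "fn_rate",
    "fp_rate",
    "score_volumes",
    "evaluate_patient",
    "cohort_report",
    "read_mask_dir",
    "read_volume_nifti",
]


@dataclass(frozen=True)
class LabeledVolume:
    """Ordered stack of binary slice masks interpreted as a voxel set."""

    data: np.ndarray  # bool, shape (n_slices, H, W)
    spacing_mm: float | None = None

    def __post_init__(self) -> None:
        d = self.data
        if d.ndim != 3 or d.dtype != bool:
            raise ValueError("data must be a 3-D boolean array (n_slices, H, W)")

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


def stack_slices(
    masks: Sequence[np.ndarray],
    order: Sequence[int] | None = None,
    spacing_mm: float | None = None,
) -> LabeledVolume:
    """Stack per-slice binary masks into a volume, sorted by axial index.

    ``order`` gives each mask's axial index; duplicates are rejected and
    the stack is normalized to increasing index so shuffled input yields
    the same volume.
    """
    masks = [np.asarray(m) for m in masks]
    if not masks:
        raise ValueError("at least one slice mask is required")
    shape = masks[0].shape
    if any(m.ndim != 2 or m.shape != shape for m in masks):
        raise ValueError("all slice masks must be 2-D with identical shape")
    if order is None:
        order = list(range(len(masks)))
    order = [int(i) for i in order]
    if len(order) != len(masks):
        raise ValueError("order must have one index per mask")
    if len(set(order)) != len(order):
        raise ValueError("duplicate axial indices in order")
    perm = np.argsort(order, kind="stable")
    data = np.stack([masks[i].astype(bool) for i in perm])
    return LabeledVolume(data=data, spacing_mm=spacing_mm)


def _as_bool(v) -> np.ndarray:
    arr = v.data if isinstance(v, LabeledVolume) else np.asarray(v)
    return arr.astype(bool)


def _counts(S, T) -> tuple[int, int, int]:
    s, t = _as_bool(S), _as_bool(T)
    if s.shape != t.shape:
        raise ValueError(f"volume shape mismatch: {s.shape} vs {t.shape}")
    inter = int(np.logical_and(s, t).sum())
    return inter, int(s.sum()), int(t.sum())


def _undefined(name: str, reason: str) -> float:
    warnings.warn(f"{name} undefined: {reason}", UndefinedMetricWarning)
    return float("nan")


def total_overlap(S, T) -> float:
    """|S n T| / |T| — fraction of ground-truth voxels recovered."""
    inter, _, nt = _counts(S, T)
    if nt == 0:
        return _undefined("total_overlap", "empty target volume")
    return inter / nt


def dice(S, T) -> float:
    """2 |S n T| / (|S| + |T|)."""
    inter, ns, nt = _counts(S, T)
    if ns + nt == 0:
        return _undefined("dice", "both volumes empty")
    return 2.0 * inter / (ns + nt)


def jaccard(S, T) -> float:
    """|S n T| / |S u T|."""
    inter, ns, nt = _counts(S, T)
    union = ns + nt - inter
    if union == 0:
        return _undefined("jaccard", "both volumes empty")
    return inter / union


def fn_rate(S, T) -> float:
    """|T - S| / |T| — ground-truth voxels missed (type II error)."""
    inter, _, nt = _counts(S, T)
    if nt == 0:
        return _undefined("fn_rate", "empty target volume")
    return (nt - inter) / nt


def fp_rate(S, T) -> float:
    """|S - T| / |S| — predicted voxels outside ground truth (type I error)."""
    inter, ns, _ = _counts(S, T)
    if ns == 0:
        return _undefined("fp_rate", "empty source volume")
    return (ns - inter) / ns


@dataclass(frozen=True)
class SegScores:
    """The five volumetric scores for one predicted/ground-truth pair."""

    total_overlap: float
    dice: float
    jaccard: float
    fn_rate: float
    fp_rate: float

    def as_dict(self) -> dict[str, float]:
        return {
            "total_overlap": self.total_overlap,
            "dice": self.dice,
            "jaccard": self.jaccard,
            "fn_rate": self.fn_rate,
            "fp_rate": self.fp_rate,
        }


def score_volumes(S, T) -> SegScores:
    """All five metrics for a predicted volume S vs ground truth T."""
    return SegScores(
        total_overlap=total_overlap(S, T),
        dice=dice(S, T),
        jaccard=jaccard(S, T),
        fn_rate=fn_rate(S, T),
        fp_rate=fp_rate(S, T),
    )


def evaluate_patient(
    pred_masks: Sequence[np.ndarray],
    gt_masks: Sequence[np.ndarray],
    min_run: int = 8,
    spacing_mm: float | None = None,
) -> SegScores:
    """Confirm runs, restore both stacks to 3D, and score the volumes.

    Predicted slices outside a run of >= min_run consecutive positive
    slices are suppressed (zeroed) before stacking, mirroring how isolated
    per-slice hits are discarded as false alarms before segmentation is
    assessed.
    """
    if len(pred_masks) != len(gt_masks):
        raise ValueError("pred and gt stacks must have the same number of slices")
    pred = [np.asarray(m).astype(bool) for m in pred_masks]
    gt = [np.asarray(m).astype(bool) for m in gt_masks]
    flags = [bool(m.any()) for m in pred]
    keep = confirmed_slice_mask(flags, min_run=min_run)
    filtered = [m if ok else np.zeros_like(m) for m, ok in zip(pred, keep)]
    S = stack_slices(filtered, spacing_mm=spacing_mm)
    T = stack_slices(gt, spacing_mm=spacing_mm)
    return score_volumes(S, T)


def cohort_report(per_patient: dict[str, SegScores]) -> pd.DataFrame:
    """Per-patient table with an unweighted 'mean' row appended."""
    if not per_patient:
        raise ValueError("no patients to report")
    df = pd.DataFrame(
        {name: s.as_dict() for name, s in per_patient.items()}
    ).T.sort_index()
    df.loc["mean"] = df.mean(axis=0)
    df.index.name = "patient"
    return df


_MASK_RE = re.compile(r"(\d+)\.png$")


def read_mask_dir(path, pattern: str = "*.png") -> list[np.ndarray]:
    """Read a directory of zero-padded per-slice binary mask PNGs.

    Files are ordered by the integer index embedded in their names; pixel
    values must be exactly 0 or 255.
    """
    import imageio.v3 as iio

    path = Path(path)
    files = sorted(path.glob(pattern), key=lambda p: int(_MASK_RE.search(p.name).group(1)))
    if not files:
        raise FileNotFoundError(f"no mask PNGs matching {pattern!r} in {path}")
    masks = []
    for f in files:
        arr = np.asarray(iio.imread(f))
        if arr.ndim == 3:
            arr = arr[..., 0]
        bad = set(np.unique(arr)) - {0, 255}
        if bad:
            raise ValueError(f"{f} is not a binary 0/255 mask (values {sorted(bad)})")
        masks.append(arr == 255)
    return masks


def read_volume_nifti(path, threshold: float = 0.5) -> LabeledVolume:
    """Read a single-file NIfTI label volume as an axial slice stack."""
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI volume, got shape {arr.shape}")
    # NIfTI is (x, y, z); reorder to (slice, row, col)
    data = np.transpose(arr, (2, 1, 0)) > threshold
    zooms = img.header.get_zooms()
    spacing = float(zooms[2]) if len(zooms) >= 3 else None
    return LabeledVolume(data=np.ascontiguousarray(data), spacing_mm=spacing)
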