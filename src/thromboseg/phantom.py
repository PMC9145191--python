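"""Seeded CTA-like phantom studies with ground-truth masks and boxes.

Each synthetic study mimics the geometry and statistics of a post-repair
abdominal-aortic-aneurysm CTA stack: 49-206 axial slices per study, a
contrast-bright lumen running through every slice, and — on a single
contiguous run of slices covering on average 20% (SD 7%) of the stack —
an eccentric thrombus annulus around the lumen whose size, aspect and
eccentricity drift smoothly from slice to slice.  The confusers that make
the clinical task hard are emulated too: the thrombus intensity sits close
to surrounding soft tissue, tissue-intensity blobs appear on every slice,
and very bright stent-graft arcs can overlap the thrombus.

Intensities are abstract 8-bit gray levels, not calibrated Hounsfield
units; only the ordering (stent >> lumen > thrombus ~ tissue) matters for
the confuser behavior.  Everything is reproducible: the same seed yields a
byte-identical study.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .box_losses import BoundingBox, read_boxes_jsonl, write_boxes_jsonl
from .detection_eval import Detection

__all__ = [
    "PhantomConfig",
    "PhantomStudy",
    "generate_study",
    "generate_cohort",
    "study_seed",
    "perturb_prediction",
    "write_study",
    "read_study",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, intensity and sampling parameters of one phantom study.

    ``thrombus_fraction`` / ``thrombus_fraction_sd`` set the Gaussian from
    which the positive-slice fraction is drawn (clipped to [0, 1]); the
    realized run is never shorter than ``min_run`` slices so the
    consecutive-slice confirmation rule is exercised.  Intensity means are
    8-bit gray levels ordered stent >> lumen > thrombus ~ tissue.
    """

    image_size: int = 512
    n_slices_range: tuple[int, int] = (49, 206)
    thrombus_fraction: float = 0.20
    thrombus_fraction_sd: float = 0.07
    min_run: int = 8
    slice_spacing_mm: float = 4.0
    tissue_mean: float = 80.0
    tissue_texture_sd: float = 6.0
    thrombus_mean: float = 92.0
    lumen_mean: float = 190.0
    stent_mean: float = 248.0
    stent_prob: float = 0.7
    n_confusers: int = 3
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        lo, hi = self.n_slices_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid n_slices_range {self.n_slices_range!r}")
        if lo < self.min_run:
            raise ValueError("n_slices_range minimum must be >= min_run")
        if not (0.0 <= self.thrombus_fraction <= 1.0):
            raise ValueError("thrombus_fraction must lie in [0, 1]")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


@dataclass(frozen=True)
class PhantomStudy:
    """One synthetic slice stack with per-slice masks and tight boxes."""

    images: np.ndarray  # uint8, (n_slices, H, W)
    masks: np.ndarray  # bool, (n_slices, H, W)
    boxes: tuple[BoundingBox | None, ...]  # tight box per slice, None if negative
    config: PhantomConfig = field(repr=False, default=PhantomConfig())

    @property
    def n_slices(self) -> int:
        return self.images.shape[0]

    @property
    def positive_slices(self) -> list[int]:
        return [i for i, b in enumerate(self.boxes) if b is not None]


def _ellipse(size: int, cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def _tight_box(mask: np.ndarray) -> BoundingBox:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    # pixel (r, c) occupies the unit cell [c, c+1) x [r, r+1)
    return BoundingBox(
        float(cols[0]), float(rows[0]), float(cols[-1] + 1), float(rows[-1] + 1)
    )


def generate_study(cfg: PhantomConfig | None = None) -> PhantomStudy:
    """Render one seeded phantom study.

    Raises ValueError when the configured geometry cannot fit the frame
    (thrombus larger than the image).
    """
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    size = cfg.image_size
    n = int(rng.integers(cfg.n_slices_range[0], cfg.n_slices_range[1] + 1))

    if cfg.thrombus_fraction <= 0.0:
        run_len, start = 0, 0
    else:
        frac = float(
            np.clip(rng.normal(cfg.thrombus_fraction, cfg.thrombus_fraction_sd), 0.0, 1.0)
        )
        run_len = min(n, max(cfg.min_run, int(round(frac * n))))
        start = int(rng.integers(0, n - run_len + 1))

    # study-level geometry
    cx0 = size * (0.5 + rng.uniform(-0.04, 0.04))
    cy0 = size * (0.5 + rng.uniform(-0.04, 0.04))
    lumen_r = size * rng.uniform(0.045, 0.06)
    outer_max = size * rng.uniform(0.11, 0.16)
    if outer_max >= size * 0.45:
        raise ValueError("infeasible geometry: thrombus larger than the frame")
    drift_amp = size * 0.02
    drift_phase = rng.uniform(0, 2 * math.pi)
    ecc_phase = rng.uniform(0, 2 * math.pi)
    aspect_phase = rng.uniform(0, 2 * math.pi)
    stent_angle0 = rng.uniform(0, 2 * math.pi)
    has_stent = rng.random() < cfg.stent_prob
    confusers = [
        (
            rng.uniform(0.15, 0.85) * size,
            rng.uniform(0.15, 0.85) * size,
            rng.uniform(0.03, 0.07) * size,
            rng.uniform(0.03, 0.07) * size,
        )
        for _ in range(cfg.n_confusers)
    ]

    images = np.empty((n, size, size), dtype=np.uint8)
    masks = np.zeros((n, size, size), dtype=bool)
    boxes: list[BoundingBox | None] = []

    yy, xx = np.mgrid[0:size, 0:size]
    for k in range(n):
        # blotchy soft-tissue background
        tissue = rng.normal(cfg.tissue_mean, cfg.tissue_texture_sd, (size, size))
        img = ndimage.gaussian_filter(tissue, sigma=size / 40.0)
        for bx, by, brx, bry in confusers:
            blob = ((xx - bx) / brx) ** 2 + ((yy - by) / bry) ** 2 <= 1.0
            img[blob] = cfg.thrombus_mean + rng.normal(0.0, 1.5)

        cx = cx0 + drift_amp * math.sin(2 * math.pi * k / n + drift_phase)
        cy = cy0 + drift_amp * math.cos(2 * math.pi * k / n + drift_phase)
        lumen = _ellipse(size, cx, cy, lumen_r, lumen_r * 0.95)

        in_run = start <= k < start + run_len
        if in_run:
            s = (k - start + 0.5) / run_len  # position along the aneurysm
            bump = math.sin(math.pi * s)
            outer_r = lumen_r + 3.0 + (outer_max - lumen_r - 3.0) * (0.35 + 0.65 * bump)
            aspect = 1.0 + 0.15 * math.sin(2 * math.pi * s + aspect_phase)
            off = 0.4 * (outer_r - lumen_r)
            ox = cx + off * math.cos(ecc_phase + 1.5 * s)
            oy = cy + off * math.sin(ecc_phase + 1.5 * s)
            outer = _ellipse(size, ox, oy, outer_r * aspect, outer_r / aspect)
            thrombus = outer & ~lumen
            img[thrombus] = cfg.thrombus_mean + rng.normal(0.0, 1.0)
        else:
            thrombus = None

        img[lumen] = cfg.lumen_mean

        if in_run and has_stent:
            # bright arc at the lumen boundary, drifting orientation
            ang = np.arctan2(yy - cy, xx - cx)
            rad = np.sqrt(((xx - cx) / 1.0) ** 2 + (yy - cy) ** 2)
            a0 = stent_angle0 + 0.05 * k
            dang = np.angle(np.exp(1j * (ang - a0)))
            arc = (np.abs(dang) < math.pi / 3) & (rad >= lumen_r) & (rad <= lumen_r + 2.5)
            img[arc] = cfg.stent_mean

        img = img + rng.normal(0.0, cfg.noise_sd, (size, size))
        images[k] = np.clip(img, 0, 255).astype(np.uint8)

        if thrombus is not None and thrombus.any():
            masks[k] = thrombus
            boxes.append(_tight_box(thrombus))
        else:
            boxes.append(None)

    return PhantomStudy(images=images, masks=masks, boxes=tuple(boxes), config=cfg)


def study_seed(master_seed: int, study_index: int) -> int:
    """Derive a per-study seed from (master_seed, study_index), below 2^31."""
    ss = np.random.SeedSequence([int(master_seed), int(study_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    n_studies: int, cfg: PhantomConfig | None = None, master_seed: int = 0
) -> list[PhantomStudy]:
    """Generate independent studies with per-study seeds derived from one master."""
    cfg = cfg or PhantomConfig()
    out = []
    for i in range(n_studies):
        study_cfg = PhantomConfig(**{**asdict(cfg), "seed": study_seed(master_seed, i)})
        out.append(generate_study(study_cfg))
    return out


def perturb_prediction(
    study: PhantomStudy,
    miss_rate: float = 0.0,
    fp_rate: float = 0.0,
    jitter_px: float = 0.0,
    morph_iter: int = 0,
    seed: int = 0,
) -> tuple[list[Detection], np.ndarray]:
    """Oracle detector: ground truth with controlled, seeded degradation.

    Positive slices are dropped with probability ``miss_rate``; negative
    slices gain a spurious detection with probability ``fp_rate``; kept
    boxes are jittered uniformly by up to ``jitter_px`` per corner and
    kept masks eroded or dilated ``morph_iter`` times.  With all rates at
    zero the prediction equals the ground truth exactly.
    """
    for name, r in (("miss_rate", miss_rate), ("fp_rate", fp_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {r!r}")
    rng = np.random.default_rng(seed)
    size = study.images.shape[1]
    masks = np.zeros_like(study.masks)
    dets: list[Detection] = []
    for k, box in enumerate(study.boxes):
        if box is not None:
            if rng.random() < miss_rate:
                continue
            if jitter_px > 0:
                j = rng.uniform(-jitter_px, jitter_px, 4)
                coords = box.as_array() + j
                x1, x2 = sorted((coords[0], coords[2]))
                y1, y2 = sorted((coords[1], coords[3]))
                box = BoundingBox(x1, y1, x2, y2)
            m = study.masks[k]
            if morph_iter > 0:
                if rng.random() < 0.5:
                    m2 = ndimage.binary_erosion(m, iterations=morph_iter)
                    m = m2 if m2.any() else m
                else:
                    m = ndimage.binary_dilation(m, iterations=morph_iter)
            masks[k] = m
            dets.append(Detection(k, box, float(0.85 + 0.14 * rng.random())))
        elif fp_rate > 0 and rng.random() < fp_rate:
            bx = rng.uniform(0.2, 0.8) * size
            by = rng.uniform(0.2, 0.8) * size
            r = rng.uniform(0.02, 0.05) * size
            blob = _ellipse(size, bx, by, r, r)
            masks[k] = blob
            dets.append(Detection(k, _tight_box(blob), float(0.5 + 0.25 * rng.random())))
    return dets, masks


# ---------------------------------------------------------------------------
# on-disk layout: slice_###.png, mask_###.png, boxes.jsonl, meta.json
# ---------------------------------------------------------------------------


def write_study(study: PhantomStudy, directory) -> None:
    """Write slices, masks (0/255 PNG), boxes (JSON lines) and metadata."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k in range(study.n_slices):
        iio.imwrite(directory / f"slice_{k:03d}.png", study.images[k])
        iio.imwrite(
            directory / f"mask_{k:03d}.png", (study.masks[k] * 255).astype(np.uint8)
        )
    records = [
        {
            "slice": k,
            "x_min": b.x_min,
            "y_min": b.y_min,
            "x_max": b.x_max,
            "y_max": b.y_max,
            "score": 1.0,
        }
        for k, b in enumerate(study.boxes)
        if b is not None
    ]
    write_boxes_jsonl(directory / "boxes.jsonl", records)
    cfg = asdict(study.config)
    cfg["n_slices_range"] = list(cfg["n_slices_range"])
    (directory / "meta.json").write_text(
        json.dumps({"n_slices": study.n_slices, "config": cfg}, indent=2)
    )


def read_study(directory) -> PhantomStudy:
    """Read back a study written by :func:`write_study`.

    Raises a clear error when the directory is truncated (missing slices,
    masks or metadata).
    """
    import imageio.v3 as iio

    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing meta.json in {directory}")
    meta = json.loads(meta_path.read_text())
    n = int(meta["n_slices"])
    cfg_dict = dict(meta["config"])
    cfg_dict["n_slices_range"] = tuple(cfg_dict["n_slices_range"])
    cfg = PhantomConfig(**cfg_dict)

    images, masks = [], []
    for k in range(n):
        spath = directory / f"slice_{k:03d}.png"
        mpath = directory / f"mask_{k:03d}.png"
        if not spath.exists() or not mpath.exists():
            raise FileNotFoundError(f"truncated study: missing slice/mask {k} in {directory}")
        images.append(np.asarray(iio.imread(spath)))
        marr = np.asarray(iio.imread(mpath))
        bad = set(np.unique(marr)) - {0, 255}
        if bad:
            raise ValueError(f"{mpath} is not a binary 0/255 mask")
        masks.append(marr == 255)

    boxes: list[BoundingBox | None] = [None] * n
    for rec in read_boxes_jsonl(directory / "boxes.jsonl"):
        boxes[int(rec["slice"])] = BoundingBox(
            rec["x_min"], rec["y_min"], rec["x_max"], rec["y_max"]
        )
    return PhantomStudy(
        images=np.stack(images).astype(np.uint8),
        masks=np.stack(masks),
        boxes=tuple(boxes),
        config=cfg,
    )
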