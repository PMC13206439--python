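"""Synthetic CT-like fixtures: slices with elliptical nodules,
per-patient grouping, controllable blur/contrast, and a simulated
teacher detector.

The generator emulates the statistical structure the toolkit consumes —
nodule counts, pixel areas, aspect ratios, slice sharpness and
contrast, patient grouping — not anatomy.  Each slice is a smoothed
random field plus a darker circular "lung" region, with white-noise
detail whose amplitude sets the contrast knob and whose optional
Gaussian blur drives the Laplacian-variance sharpness measure below or
above the 500 threshold.  Nodules are bright filled ellipses drawn
fully inside the image; the recorded per-nodule area is the rasterized
mask foreground count.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import draw

from .annotations import Box, Nodule, SliceRecord
from .modeldriven import DetectionSummary

__all__ = ["FixtureSpec", "generate_dataset", "simulate_teacher"]

#: typical chest-CT in-plane pixel spacing, mm/px
DEFAULT_SPACING_MM = 0.7


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``nodule_count_distribution`` is a probability vector over per-slice
    nodule counts 0-5; areas are rasterized mask areas in px^2, aspect
    ratios are box-elongation targets (>= 1), ``blur_sigma_range`` is
    the Gaussian blur applied to the slice texture in px, and
    ``contrast_range`` the target intensity standard deviation inside
    the lung region (8-bit units).
    """

    n_patients: int = 12
    slices_per_patient: int = 6
    nodule_count_distribution: dict[int, float] = field(
        default_factory=lambda: {0: 0.35, 1: 0.30, 2: 0.15, 3: 0.10, 4: 0.06, 5: 0.04}
    )
    area_range_px: tuple[float, float] = (150.0, 2500.0)
    aspect_ratio_range: tuple[float, float] = (1.0, 3.0)
    blur_sigma_range: tuple[float, float] = (0.0, 3.0)
    contrast_range: tuple[float, float] = (12.0, 70.0)
    image_size: int = 512
    spacing_mm: float = DEFAULT_SPACING_MM
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.array(
            [self.nodule_count_distribution.get(k, 0.0) for k in range(6)]
        )
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("nodule_count_distribution must be a probability vector")
        for name in ("area_range_px", "aspect_ratio_range",
                     "blur_sigma_range", "contrast_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: low {lo} exceeds high {hi}")
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if self.n_patients <= 0 or self.slices_per_patient <= 0:
            raise ValueError("patient/slice counts must be positive")

    @property
    def count_probs(self) -> np.ndarray:
        return np.array(
            [self.nodule_count_distribution.get(k, 0.0) for k in range(6)]
        )


def _check_geometry(spec: FixtureSpec) -> None:
    area_hi = spec.area_range_px[1]
    ar_hi = spec.aspect_ratio_range[1]
    # largest semi-major axis the spec can request
    a_max = math.sqrt(area_hi * ar_hi / math.pi)
    if 2 * a_max + 8 >= spec.image_size:
        raise ValueError(
            f"infeasible geometry: a nodule of area {area_hi} px^2 at aspect "
            f"ratio {ar_hi} needs a major axis of {2 * a_max:.0f} px, which "
            f"does not fit in a {spec.image_size} px image"
        )


def _background(spec: FixtureSpec, rng: np.random.Generator,
                contrast: float, blur_sigma: float
                ) -> tuple[np.ndarray, np.ndarray]:
    """Slice background and its circular lung mask."""
    size = spec.image_size
    yy, xx = np.mgrid[0:size, 0:size]
    center = size / 2.0
    lung = (yy - center) ** 2 + (xx - center) ** 2 <= (0.40 * size) ** 2
    base = np.where(lung, 70.0, 180.0)
    smooth = ndimage.gaussian_filter(rng.normal(size=(size, size)), sigma=size / 32)
    detail = rng.normal(size=(size, size))
    texture = 0.5 * smooth / max(smooth.std(), 1e-12) + 1.0 * detail
    if blur_sigma > 0:
        texture = ndimage.gaussian_filter(texture, sigma=blur_sigma)
    texture *= contrast / max(texture[lung].std(), 1e-12)
    return base + texture, lung


def _place_nodule(
    spec: FixtureSpec,
    rng: np.random.Generator,
    occupied: list[Box],
) -> tuple[np.ndarray, np.ndarray, Box]:
    """Rasterize one elliptical nodule that fits inside the image and
    does not overlap previously placed ones.  Size and shape are
    resampled on every placement attempt so crowded slices can still be
    populated from the low end of the requested ranges."""
    size = spec.image_size
    area = ar = None
    for _ in range(200):
        area = rng.uniform(*spec.area_range_px)
        ar = rng.uniform(*spec.aspect_ratio_range)
        b = math.sqrt(area / (math.pi * ar))
        a = ar * b
        margin = a + 3.0
        if 2 * margin >= size:
            raise ValueError("infeasible geometry: nodule too large for image")
        cy = rng.uniform(margin, size - margin)
        cx = rng.uniform(margin, size - margin)
        theta = rng.uniform(0, math.pi)
        rr, cc = draw.ellipse(cy, cx, a, b, shape=(size, size), rotation=theta)
        if len(rr) == 0:
            continue
        box = Box(float(cc.min()), float(rr.min()),
                  float(cc.max() + 1), float(rr.max() + 1))
        if all(_boxes_disjoint(box, other) for other in occupied):
            return rr, cc, box
    raise ValueError(
        "infeasible geometry: could not place a non-overlapping nodule "
        f"of area {area:.0f} px^2 after 200 attempts"
    )


def _boxes_disjoint(a: Box, b: Box) -> bool:
    return (
        a.x_max <= b.x_min or b.x_max <= a.x_min
        or a.y_max <= b.y_min or b.y_max <= a.y_min
    )


def generate_dataset(spec: FixtureSpec) -> list[SliceRecord]:
    """Generate all slices of a synthetic dataset.

    Deterministic given ``spec.seed``; every nodule's mask is a filled
    ellipse fully inside the image, and the recorded per-nodule
    ``area_px`` equals its mask foreground pixel count.
    """
    _check_geometry(spec)
    rng = np.random.default_rng(spec.seed)
    records: list[SliceRecord] = []
    for p in range(spec.n_patients):
        patient_id = f"P{p:04d}"
        for s in range(spec.slices_per_patient):
            slice_id = f"{patient_id}_S{s:03d}"
            contrast = rng.uniform(*spec.contrast_range)
            blur_sigma = rng.uniform(*spec.blur_sigma_range)
            image, lung = _background(spec, rng, contrast, blur_sigma)
            n_nodules = int(rng.choice(6, p=spec.count_probs))
            mask = np.zeros((spec.image_size, spec.image_size), dtype=np.uint8)
            nodules: list[Nodule] = []
            occupied: list[Box] = []
            for _ in range(n_nodules):
                rr, cc, box = _place_nodule(spec, rng, occupied)
                occupied.append(box)
                mask[rr, cc] = 1
                image[rr, cc] += 70.0
                nodules.append(Nodule.from_box(box, area_px=float(len(rr))))
            records.append(
                SliceRecord(
                    patient_id=patient_id,
                    slice_id=slice_id,
                    image=np.clip(np.round(image), 0, 255).astype(np.uint8),
                    spacing_mm=spec.spacing_mm,
                    nodules=nodules,
                    mask=mask,
                    lung_mask=lung.astype(np.uint8),
                )
            )
    return records


def _beta_mean(rng: np.random.Generator, mean: float,
               concentration: float = 12.0) -> float:
    """Beta draw with the given mean; degenerate means return exactly."""
    if mean <= 0.0:
        return 0.0
    if mean >= 1.0:
        return 1.0
    return float(rng.beta(mean * concentration, (1.0 - mean) * concentration))


def simulate_teacher(
    records: Sequence[SliceRecord],
    quality_of_teacher: float,
    seed: int = 0,
) -> list[DetectionSummary]:
    """Simulate a teacher detector of adjustable quality in [0, 1].

    At quality 1 predictions equal the ground truth with confidence 1.0
    and no false positives; as quality drops, detections are missed
    (each ground-truth box is found with probability equal to the
    quality), surviving boxes are jittered, confidences fall (Beta
    distributed with mean equal to the quality), and spurious boxes
    appear at a Poisson rate of 0.4 per slice at quality 0.  At least
    five pre-NMS candidate scores are always emitted per slice.
    """
    if not 0.0 <= quality_of_teacher <= 1.0:
        raise ValueError("quality_of_teacher must be in [0, 1]")
    q = quality_of_teacher
    rng = np.random.default_rng(seed)
    summaries: list[DetectionSummary] = []
    for record in records:
        size = record.image.shape[0] if record.image is not None else 512
        boxes: list[Box] = []
        confs: list[float] = []
        for nodule in record.nodules:
            if rng.random() >= q:
                continue
            jitter = (1.0 - q) * 0.15
            gt = nodule.box
            dx = rng.normal(0, jitter * gt.width)
            dy = rng.normal(0, jitter * gt.height)
            boxes.append(
                Box(gt.x_min + dx, gt.y_min + dy,
                    gt.x_max + dx, gt.y_max + dy).clip(size, size)
            )
            confs.append(_beta_mean(rng, q))
        n_fp = int(rng.poisson(0.4 * (1.0 - q)))
        for _ in range(n_fp):
            w = rng.uniform(8, 40)
            h = rng.uniform(8, 40)
            x = rng.uniform(0, size - w)
            y = rng.uniform(0, size - h)
            boxes.append(Box(x, y, x + w, y + h))
            confs.append(_beta_mean(rng, max(0.05, 0.4 * (1 - q))))
        # background pre-NMS candidates that never survived NMS; a
        # perfect teacher assigns them exactly zero score
        n_bg = max(5, 8 - len(confs))
        bg_mean = 0.3 * (1.0 - q)
        pre_nms = list(confs) + [
            _beta_mean(rng, bg_mean) for _ in range(n_bg)
        ]
        summaries.append(
            DetectionSummary(
                slice_id=record.slice_id,
                boxes=boxes,
                confidences=confs,
                n_gt=len(record.nodules),
                pre_nms_scores=pre_nms,
            )
        )
    return summaries
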