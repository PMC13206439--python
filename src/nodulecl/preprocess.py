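"""Slice quality assessment, contrast enhancement, geometric
normalization, nodule filtering, and the patient-level splitting and
subsampling protocols.

All sampling and splitting here is patient-atomic (no patient's slices
ever straddle two subsets) and deterministic given a seed.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage import exposure, transform, util

from .annotations import Box, Nodule, SliceRecord, nodule_diameter_mm

__all__ = [
    "QualityMetrics",
    "QualityThresholds",
    "SplitAssignment",
    "PadResizeTransform",
    "window_hu",
    "compute_quality",
    "apply_clahe",
    "pad_resize",
    "filter_small_nodules",
    "sample_slices",
    "split_patients",
    "teacher_split",
    "proportional_subsets",
    "fixed_size_subset",
]

logger = logging.getLogger(__name__)

QUALITY_TIERS = ("high", "medium", "low")


@dataclass(frozen=True)
class QualityThresholds:
    """Decision boundaries for the slice-quality tiers.

    A slice is *high* quality when it is both sharp (Laplacian variance
    above ``laplacian_high``) and well contrasted (contrast above
    ``contrast_high``); it is *low* quality when either metric falls at
    or below the corresponding low boundary; otherwise *medium*.  The
    high boundaries (500 / 30 on 8-bit intensities) are the published
    operating point; the low boundaries default to roughly a third of
    them.
    """

    laplacian_high: float = 500.0
    contrast_high: float = 30.0
    laplacian_low: float = 150.0
    contrast_low: float = 15.0


@dataclass(frozen=True)
class QualityMetrics:
    lung_coverage: float
    intensity_heterogeneity: float
    laplacian_variance: float
    contrast: float
    quality_tier: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.lung_coverage <= 1.0:
            raise ValueError("lung_coverage must be in [0, 1]")
        if self.laplacian_variance < 0:
            raise ValueError("laplacian_variance must be non-negative")
        if self.quality_tier not in QUALITY_TIERS:
            raise ValueError(f"unknown quality tier {self.quality_tier!r}")


def window_hu(
    image: np.ndarray, hu_min: float = -1000.0, hu_max: float = 400.0
) -> np.ndarray:
    """Window an HU-valued slice to the lung window and map it linearly
    to 8-bit.  Already-8-bit images pass through unchanged."""
    image = np.asarray(image)
    if image.dtype == np.uint8:
        return image
    clipped = np.clip(image.astype(np.float64), hu_min, hu_max)
    scaled = (clipped - hu_min) / (hu_max - hu_min) * 255.0
    return np.round(scaled).astype(np.uint8)


def _quality_tier(
    laplacian_variance: float, contrast: float, thresholds: QualityThresholds
) -> str:
    if (
        laplacian_variance > thresholds.laplacian_high
        and contrast > thresholds.contrast_high
    ):
        return "high"
    if (
        laplacian_variance <= thresholds.laplacian_low
        or contrast <= thresholds.contrast_low
    ):
        return "low"
    return "medium"


def compute_quality(
    record: SliceRecord,
    thresholds: QualityThresholds = QualityThresholds(),
) -> QualityMetrics:
    """Compute per-slice quality metrics and assign a quality tier.

    The sharpness measure is the variance of the 3x3 discrete Laplacian
    response over the lung region; the contrast measure (and the
    intensity-heterogeneity measure, which coincides with it under this
    operationalization) is the intensity standard deviation within the
    lung region.  If the record carries no lung mask the whole image is
    treated as lung.  The result is stored on ``record.quality`` and
    returned.
    """
    if record.image is None:
        raise ValueError(f"slice {record.slice_id} has no image")
    image = window_hu(record.image).astype(np.float64)
    if record.lung_mask is not None:
        region = np.asarray(record.lung_mask) > 0
        if region.shape != image.shape:
            raise ValueError("lung mask shape does not match image shape")
        coverage = float(region.mean())
    else:
        region = np.ones(image.shape, dtype=bool)
        coverage = 1.0
    if not region.any():
        metrics = QualityMetrics(coverage, 0.0, 0.0, 0.0, "low")
        record.quality = metrics
        return metrics
    contrast = float(image[region].std())
    lap = ndimage.laplace(image)
    lap_var = float(lap[region].var())
    tier = _quality_tier(lap_var, contrast, thresholds)
    metrics = QualityMetrics(
        lung_coverage=coverage,
        intensity_heterogeneity=contrast,
        laplacian_variance=lap_var,
        contrast=contrast,
        quality_tier=tier,
    )
    record.quality = metrics
    return metrics


def apply_clahe(
    image: np.ndarray,
    clip_limit: float = 0.02,
    tile_grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit
    single-channel image.

    ``clip_limit`` follows scikit-image's normalized convention (fraction
    of the per-tile histogram), default 0.02, with an 8x8 tile grid.
    HU-valued input is lung-windowed to 8-bit first.  Constant images
    are returned unchanged.
    """
    image = window_hu(np.asarray(image))
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if image.std() == 0:
        return image.copy()
    kernel = (
        max(1, image.shape[0] // tile_grid[0]),
        max(1, image.shape[1] // tile_grid[1]),
    )
    out = exposure.equalize_adapthist(image, kernel_size=kernel, clip_limit=clip_limit)
    return np.round(out * 255.0).astype(np.uint8)


@dataclass(frozen=True)
class PadResizeTransform:
    """Affine map applied by :func:`pad_resize`: uniform scale then a
    translation from symmetric padding.  Invertible on the content
    region."""

    scale: float
    pad_x: float
    pad_y: float

    def apply_box(self, box: Box) -> Box:
        return Box(
            box.x_min * self.scale + self.pad_x,
            box.y_min * self.scale + self.pad_y,
            box.x_max * self.scale + self.pad_x,
            box.y_max * self.scale + self.pad_y,
        )

    def invert_box(self, box: Box) -> Box:
        return Box(
            (box.x_min - self.pad_x) / self.scale,
            (box.y_min - self.pad_y) / self.scale,
            (box.x_max - self.pad_x) / self.scale,
            (box.y_max - self.pad_y) / self.scale,
        )


def _resize_raster(arr: np.ndarray, shape: tuple[int, int], order: int) -> np.ndarray:
    out = transform.resize(
        arr.astype(np.float64),
        shape,
        order=order,
        anti_aliasing=(order > 0 and shape[0] < arr.shape[0]),
        preserve_range=True,
    )
    if np.issubdtype(arr.dtype, np.integer) or arr.dtype == bool:
        return np.round(out).astype(arr.dtype)
    return out.astype(arr.dtype)


def pad_resize(record: SliceRecord, target: int) -> tuple[SliceRecord, PadResizeTransform]:
    """Scale a slice to fit a ``target`` x ``target`` canvas preserving
    aspect ratio, centring the content with symmetric zero padding, and
    carry every annotation through the same affine map.

    Returns the transformed record (a copy) and the transform, whose
    ``invert_box`` recovers original-space boxes.  Pixel spacing is
    divided by the scale; nodule areas are multiplied by its square.
    """
    if target <= 0:
        raise ValueError("target must be positive")
    if record.image is None:
        raise ValueError("record has no image")
    h, w = record.image.shape[:2]
    s = target / max(h, w)
    new_h, new_w = round(h * s), round(w * s)
    pad_y = (target - new_h) // 2
    pad_x = (target - new_w) // 2
    tfm = PadResizeTransform(scale=s, pad_x=float(pad_x), pad_y=float(pad_y))

    def place(arr: np.ndarray, order: int) -> np.ndarray:
        resized = _resize_raster(arr, (new_h, new_w), order)
        canvas = np.zeros((target, target), dtype=arr.dtype)
        canvas[pad_y : pad_y + new_h, pad_x : pad_x + new_w] = resized
        return canvas

    image = place(record.image, order=1)
    mask = place(record.mask, order=0) if record.mask is not None else None
    lung = place(record.lung_mask, order=0) if record.lung_mask is not None else None
    nodules = [
        Nodule(box=tfm.apply_box(n.box), area_px=n.area_px * s * s,
               aspect_ratio=n.aspect_ratio)
        for n in record.nodules
    ]
    new_record = replace(
        record,
        image=image,
        mask=mask,
        lung_mask=lung,
        nodules=nodules,
        spacing_mm=record.spacing_mm / s,
        quality=None,
    )
    return new_record, tfm


def filter_small_nodules(
    records: Iterable[SliceRecord], min_diameter_mm: float = 3.0
) -> list[SliceRecord]:
    """Drop nodules smaller than ``min_diameter_mm`` (strict ``<``);
    slices themselves are never removed, so a slice whose only nodule is
    sub-threshold becomes nodule-free."""
    out = []
    for record in records:
        if record.spacing_mm is None or record.spacing_mm <= 0:
            raise ValueError(f"slice {record.slice_id} has no pixel spacing")
        kept = [
            n
            for n in record.nodules
            if nodule_diameter_mm(n, record.spacing_mm) >= min_diameter_mm
        ]
        out.append(replace(record, nodules=kept))
    return out


def _quality_sort_key(record: SliceRecord) -> tuple:
    tier_rank = {"high": 0, "medium": 1, "low": 2}[record.quality.quality_tier]
    # best first: high tier, then sharper, then more contrast
    return (
        tier_rank,
        -record.quality.laplacian_variance,
        -record.quality.contrast,
    )


def sample_slices(
    records: Sequence[SliceRecord], ratio: float = 2.0, seed: int = 0
) -> list[SliceRecord]:
    """Nodule-oriented slice sampling: keep every nodule-bearing slice
    and the best-quality non-nodule slices at approximately ``ratio``
    negatives per positive (default 1:2).

    Requires quality metrics on every record.  If fewer negatives exist
    than the target, all are kept and a warning is logged.
    """
    for record in records:
        if record.quality is None:
            raise ValueError(
                f"slice {record.slice_id} has no quality metrics; "
                "run compute_quality first"
            )
    positives = [r for r in records if r.has_nodule]
    negatives = [r for r in records if not r.has_nodule]
    n_target = int(round(ratio * len(positives)))
    rng = np.random.default_rng(seed)
    tie = rng.permutation(len(negatives))
    order = sorted(range(len(negatives)),
                   key=lambda i: (_quality_sort_key(negatives[i]), tie[i]))
    if len(negatives) < n_target:
        logger.warning(
            "only %d non-nodule slices available for a target of %d; keeping all",
            len(negatives), n_target,
        )
        chosen = list(range(len(negatives)))
    else:
        chosen = order[:n_target]
    kept_ids = {negatives[i].slice_id for i in chosen}
    return [r for r in records if r.has_nodule or r.slice_id in kept_ids]


@dataclass(frozen=True)
class SplitAssignment:
    """Patient-level partition into named subsets."""

    assignment: dict[str, str]
    fractions: tuple[float, ...]
    subset_names: tuple[str, ...]
    seed: int

    def patients(self, subset: str) -> list[str]:
        return sorted(p for p, s in self.assignment.items() if s == subset)

    def subset_of(self, patient_id: str) -> str:
        return self.assignment[patient_id]

    def select(self, records: Iterable[SliceRecord], subset: str) -> list[SliceRecord]:
        return [r for r in records if self.assignment[r.patient_id] == subset]


def _patient_slice_counts(records: Iterable[SliceRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in records:
        counts[r.patient_id] = counts.get(r.patient_id, 0) + 1
    return counts


def _greedy_partition(
    counts: dict[str, int],
    fractions: Sequence[float],
    names: Sequence[str],
    seed: int,
) -> dict[str, str]:
    """Seeded shuffle then greedy assignment by slice count: each patient
    goes to the subset with the largest remaining slice deficit."""
    total = sum(counts.values())
    rng = np.random.default_rng(seed)
    patients = sorted(counts)
    rng.shuffle(patients)
    targets = [f * total for f in fractions]
    filled = [0.0] * len(fractions)
    assignment: dict[str, str] = {}
    for patient in patients:
        deficits = [t - f for t, f in zip(targets, filled)]
        idx = int(np.argmax(deficits))  # ties -> earlier subset
        assignment[patient] = names[idx]
        filled[idx] += counts[patient]
    return assignment


def split_patients(
    records: Sequence[SliceRecord],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    subset_names: tuple[str, ...] = ("train", "val", "test"),
) -> SplitAssignment:
    """Patient-level train/val/test split targeting the given slice
    fractions (default 80/10/10)."""
    if len(fractions) != len(subset_names):
        raise ValueError("fractions and subset_names must align")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    counts = _patient_slice_counts(records)
    if len(counts) < len(subset_names):
        raise ValueError(
            f"need at least {len(subset_names)} patients, got {len(counts)}"
        )
    assignment = _greedy_partition(counts, fractions, subset_names, seed)
    return SplitAssignment(
        assignment=assignment,
        fractions=tuple(fractions),
        subset_names=tuple(subset_names),
        seed=seed,
    )


def teacher_split(
    train_records: Sequence[SliceRecord], seed: int = 0
) -> tuple[list[SliceRecord], list[SliceRecord], list[SliceRecord]]:
    """Split the training pool for teacher-based difficulty scoring.

    20% of patients are held out purely for scoring; of the remaining
    80%, 90% trains the teacher and 10% validates it — i.e. 72% / 8% /
    20% of the pool overall.  Returns ``(teacher_train, teacher_val,
    scoring_heldout)`` record lists.
    """
    outer = split_patients(
        train_records, fractions=(0.8, 0.2), seed=seed,
        subset_names=("teacher_pool", "scoring_heldout"),
    )
    pool = outer.select(train_records, "teacher_pool")
    heldout = outer.select(train_records, "scoring_heldout")
    inner = split_patients(
        pool, fractions=(0.9, 0.1), seed=seed + 1,
        subset_names=("teacher_train", "teacher_val"),
    )
    return (
        inner.select(pool, "teacher_train"),
        inner.select(pool, "teacher_val"),
        heldout,
    )


def proportional_subsets(
    train_records: Sequence[SliceRecord],
    fraction: float,
    n_folds: int = 3,
    seed: int = 0,
) -> list[list[SliceRecord]]:
    """Patient-level proportional subsampling: ``n_folds`` independent
    subsets each holding about ``fraction`` of the training slices
    (whole patients only)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    counts = _patient_slice_counts(train_records)
    total = sum(counts.values())
    target = fraction * total
    folds: list[list[SliceRecord]] = []
    for k in range(n_folds):
        if fraction == 1.0:
            folds.append(list(train_records))
            continue
        rng = np.random.default_rng(seed + k)
        patients = sorted(counts)
        rng.shuffle(patients)
        chosen: set[str] = set()
        acc = 0
        for patient in patients:
            c = counts[patient]
            # include the boundary patient only if it brings us closer
            if acc + c <= target or abs(acc + c - target) < abs(acc - target):
                chosen.add(patient)
                acc += c
            if acc >= target:
                break
        folds.append([r for r in train_records if r.patient_id in chosen])
    return folds


def fixed_size_subset(
    train_records: Sequence[SliceRecord], n_slices: int, seed: int = 42
) -> list[SliceRecord]:
    """Fixed-budget subset: patients are appended in seeded random order
    until the slice budget is reached; the boundary patient is included
    whole, so the result holds at least ``n_slices`` slices."""
    counts = _patient_slice_counts(train_records)
    total = sum(counts.values())
    if n_slices > total:
        raise ValueError(f"requested {n_slices} slices but only {total} exist")
    rng = np.random.default_rng(seed)
    patients = sorted(counts)
    rng.shuffle(patients)
    chosen: set[str] = set()
    acc = 0
    for patient in patients:
        chosen.add(patient)
        acc += counts[patient]
        if acc >= n_slices:
            break
    return [r for r in train_records if r.patient_id in chosen]
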