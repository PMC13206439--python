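"""Canonical geometry and label I/O.

Coordinate convention used throughout the package: 0-based pixel
coordinates, half-open intervals ``[x_min, x_max) x [y_min, y_max)``,
with ``x`` indexing columns and ``y`` indexing rows.  Under this
convention the area of a box is exactly ``(x_max - x_min) *
(y_max - y_min)`` pixels and a single foreground pixel at row ``r``,
column ``c`` has the box ``(c, r, c + 1, r + 1)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from scipy import ndimage

if TYPE_CHECKING:  # pragma: no cover - avoids a circular import at run time
    from .preprocess import QualityMetrics

__all__ = [
    "Box",
    "Nodule",
    "SliceRecord",
    "mask_to_boxes",
    "nodule_diameter_mm",
    "read_labels",
    "write_labels",
]

# 8-connectivity structuring element for blob labelling
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Box:
    """Axis-aligned bounding box, half-open pixel intervals."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def clip(self, image_width: float, image_height: float) -> "Box":
        """Clip to image bounds; raises if nothing remains."""
        return Box(
            max(self.x_min, 0.0),
            max(self.y_min, 0.0),
            min(self.x_max, image_width),
            min(self.y_max, image_height),
        )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass
class Nodule:
    """One nodule on one slice.

    ``area_px`` is the mask foreground pixel count when a mask is
    available, otherwise the box area.  ``aspect_ratio`` is
    ``max(w/h, h/w)`` of the bounding box, always >= 1.
    """

    box: Box
    area_px: float
    aspect_ratio: float

    def __post_init__(self) -> None:
        if self.area_px <= 0:
            raise ValueError("nodule area must be positive")
        if self.aspect_ratio < 1.0:
            raise ValueError("aspect ratio must be >= 1")

    @classmethod
    def from_box(cls, box: Box, area_px: float | None = None) -> "Nodule":
        w, h = box.width, box.height
        return cls(
            box=box,
            area_px=box.area if area_px is None else area_px,
            aspect_ratio=max(w / h, h / w),
        )

    def diameter_mm(self, spacing_mm: float) -> float:
        return nodule_diameter_mm(self, spacing_mm)


@dataclass
class SliceRecord:
    """One CT slice with its image, provenance and annotations."""

    patient_id: str
    slice_id: str
    image: np.ndarray | None
    spacing_mm: float
    nodules: list[Nodule] = field(default_factory=list)
    mask: np.ndarray | None = None
    lung_mask: np.ndarray | None = None
    quality: "QualityMetrics | None" = None

    def __post_init__(self) -> None:
        if self.spacing_mm is not None and self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")

    @property
    def has_nodule(self) -> bool:
        return len(self.nodules) > 0

    @property
    def boxes(self) -> list[Box]:
        return [n.box for n in self.nodules]


def mask_to_boxes(mask: np.ndarray) -> list[Box]:
    """Derive tight bounding boxes from a binary segmentation mask.

    One box per 8-connected foreground component, in half-open pixel
    coordinates.  Boxes are returned in labelling order (top-left first).
    """
    mask = np.asarray(mask)
    values = np.unique(mask)
    if not np.all(np.isin(values, (0, 1))):
        raise ValueError(f"mask is not binary; values found: {values[:10]}")
    labeled, n = ndimage.label(mask, structure=_STRUCTURE_8)
    boxes: list[Box] = []
    for sl in ndimage.find_objects(labeled):
        if sl is None:
            continue
        rows, cols = sl
        # slice stops are exclusive, matching the half-open convention
        boxes.append(Box(float(cols.start), float(rows.start),
                         float(cols.stop), float(rows.stop)))
    return boxes


def nodules_from_mask(mask: np.ndarray) -> list[Nodule]:
    """Per-component nodules with mask-derived pixel areas."""
    mask = np.asarray(mask)
    values = np.unique(mask)
    if not np.all(np.isin(values, (0, 1))):
        raise ValueError("mask is not binary")
    labeled, n = ndimage.label(mask, structure=_STRUCTURE_8)
    nodules = []
    for lab, sl in enumerate(ndimage.find_objects(labeled), start=1):
        if sl is None:
            continue
        rows, cols = sl
        box = Box(float(cols.start), float(rows.start),
                  float(cols.stop), float(rows.stop))
        area = int(np.count_nonzero(labeled[sl] == lab))
        nodules.append(Nodule.from_box(box, area_px=area))
    return nodules


def nodule_diameter_mm(nodule: Nodule | Box, spacing_mm: float) -> float:
    """Nodule diameter in mm: the larger axis-aligned box extent times
    the in-plane pixel spacing."""
    if spacing_mm is None or spacing_mm <= 0:
        raise ValueError("spacing_mm must be a positive number")
    box = nodule.box if isinstance(nodule, Nodule) else nodule
    return max(box.width, box.height) * spacing_mm


def _image_wh(image_size: int | tuple[int, int]) -> tuple[int, int]:
    if isinstance(image_size, (tuple, list)):
        w, h = image_size
    else:
        w = h = int(image_size)
    if w <= 0 or h <= 0:
        raise ValueError("image_size must be positive")
    return int(w), int(h)


def read_labels(path: str | Path, image_size: int | tuple[int, int]) -> list[Box]:
    """Read YOLO-format labels (``class cx cy w h``, normalized to [0,1])
    and return pixel-space boxes for the given image size.

    ``image_size`` is a single integer for square images or ``(width,
    height)``.  Malformed rows are rejected with their line number.
    """
    width, height = _image_wh(image_size)
    path = Path(path)
    boxes: list[Box] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        try:
            cls = int(parts[0])
            cx, cy, w, h = (float(p) for p in parts[1:])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        if cls < 0:
            raise ValueError(f"{path}:{lineno}: negative class index")
        for name, v in zip(("cx", "cy", "w", "h"), (cx, cy, w, h)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{path}:{lineno}: {name}={v} outside [0, 1]")
        if w <= 0 or h <= 0:
            raise ValueError(f"{path}:{lineno}: non-positive box size")
        boxes.append(
            Box(
                (cx - w / 2.0) * width,
                (cy - h / 2.0) * height,
                (cx + w / 2.0) * width,
                (cy + h / 2.0) * height,
            ).clip(width, height)
        )
    return boxes


def write_labels(
    boxes: Iterable[Box],
    image_size: int | tuple[int, int],
    path: str | Path,
    class_index: int = 0,
) -> None:
    """Write boxes as YOLO-format rows, normalized to [0, 1].

    Coordinates are written with enough digits that a write/read
    round-trip recovers each coordinate to well within half a pixel.
    """
    width, height = _image_wh(image_size)
    lines = []
    for box in boxes:
        cx = (box.x_min + box.x_max) / 2.0 / width
        cy = (box.y_min + box.y_max) / 2.0 / height
        w = box.width / width
        h = box.height / height
        lines.append(f"{class_index} {cx:.10g} {cy:.10g} {w:.10g} {h:.10g}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
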