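"""Handcrafted per-slice difficulty: the sum of four clinically
interpretable factors (nodule count, smallest-nodule size, shape
irregularity, image quality).

c_manual = f_cnt + f_size + f_shape + f_qual, bounded in [2.0, 11.0].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotations import Nodule, SliceRecord
from .preprocess import QualityMetrics

__all__ = [
    "ManualFactors",
    "f_cnt",
    "f_size",
    "f_shape",
    "f_qual",
    "score_manual",
    "DEFAULT_IRREGULARITY_THRESHOLD",
]

#: aspect ratio above which a nodule counts as irregular
DEFAULT_IRREGULARITY_THRESHOLD = 2.0


@dataclass(frozen=True)
class ManualFactors:
    f_cnt: float
    f_size: float
    f_shape: float
    f_qual: float

    @property
    def c_manual(self) -> float:
        return self.f_cnt + self.f_size + self.f_shape + self.f_qual


def f_cnt(nodules: Sequence[Nodule]) -> float:
    """Nodule-count factor: 0.5 for nodule-free slices, 1.0 for one
    nodule, 2.5 for 2-3 nodules, 4.0 for four or more."""
    n = len(nodules)
    if n == 0:
        return 0.5
    if n == 1:
        return 1.0
    if n <= 3:
        return 2.5
    return 4.0


def f_size(nodules: Sequence[Nodule]) -> float:
    """Smallest-nodule size factor: 0.5 with no nodule, 1.0 when the
    minimum nodule area exceeds 1000 px, 2.0 in the 400-1000 px band
    (inclusive at both ends), 3.0 below 400 px.

    Areas are pixel areas at the stored 512x512 resolution — mask
    foreground counts when masks exist, box areas otherwise.
    """
    if not nodules:
        return 0.5
    smallest = min(n.area_px for n in nodules)
    if smallest > 1000.0:
        return 1.0
    if smallest >= 400.0:
        return 2.0
    return 3.0


def f_shape(
    nodules: Sequence[Nodule],
    irregularity_threshold: float = DEFAULT_IRREGULARITY_THRESHOLD,
) -> float:
    """Shape-irregularity factor: 0.5 with no irregular nodule, 1.0 with
    exactly one, 2.0 with several, where a nodule is irregular when its
    box aspect ratio exceeds ``irregularity_threshold``."""
    n_irregular = sum(1 for n in nodules if n.aspect_ratio > irregularity_threshold)
    if n_irregular == 0:
        return 0.5
    if n_irregular == 1:
        return 1.0
    return 2.0


def f_qual(quality: QualityMetrics | str) -> float:
    """Image-quality factor from the quality tier: high -> 0.5,
    medium -> 1.0, low -> 2.0."""
    tier = quality if isinstance(quality, str) else quality.quality_tier
    try:
        return {"high": 0.5, "medium": 1.0, "low": 2.0}[tier]
    except KeyError:
        raise ValueError(f"unknown quality tier {tier!r}") from None


def score_manual(
    record: SliceRecord,
    irregularity_threshold: float = DEFAULT_IRREGULARITY_THRESHOLD,
) -> ManualFactors:
    """Handcrafted difficulty of one slice; the four component factors
    are kept for audit."""
    if record.quality is None:
        raise ValueError(
            f"slice {record.slice_id} has no quality metrics; "
            "run compute_quality first"
        )
    return ManualFactors(
        f_cnt=f_cnt(record.nodules),
        f_size=f_size(record.nodules),
        f_shape=f_shape(record.nodules, irregularity_threshold),
        f_qual=f_qual(record.quality),
    )
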