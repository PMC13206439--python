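"""Model-driven per-slice difficulty from a teacher detector's
prediction summaries.

The raw score combines three penalties — low mean confidence, a count
discrepancy between predictions and ground truth, and overly dense
prediction —

    c_det = clip( lambda1 * (1 - p_bar)
                + lambda2 * |N_pred - N_gt| / max(N_gt, 1)
                + lambda3 * min(0.5 * N_pred, 2.0),
                clip_low, clip_high )

with lambda1 = lambda2 = 3.0, lambda3 = 1.0 and clipping to [0.5, 8.0]
by default.  p_bar is the mean confidence of post-NMS boxes when any
survive; with no surviving boxes it is one minus the mean of the top-5
pre-NMS candidate scores (padded with zeros below five candidates), so
that a high p_bar always means a confident detector.

Scores are only meaningful on slices the teacher never trained on;
:func:`score_heldout` enforces that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import Box

__all__ = [
    "DetectionSummary",
    "ModelDifficultyParams",
    "mean_confidence",
    "score_model",
    "score_heldout",
]

logger = logging.getLogger(__name__)


@dataclass
class DetectionSummary:
    """Teacher-detector outputs for one slice: post-NMS boxes with
    confidences, optional pre-NMS candidate scores, and the slice's
    ground-truth nodule count."""

    slice_id: str
    boxes: list[Box]
    confidences: list[float]
    n_gt: int
    pre_nms_scores: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.boxes) != len(self.confidences):
            raise ValueError("boxes and confidences must align")
        if any(not 0.0 <= c <= 1.0 for c in self.confidences):
            raise ValueError("confidences must lie in [0, 1]")
        if any(not 0.0 <= s <= 1.0 for s in self.pre_nms_scores):
            raise ValueError("pre-NMS scores must lie in [0, 1]")
        if self.n_gt < 0:
            raise ValueError("n_gt must be non-negative")
        self.pre_nms_scores = sorted(self.pre_nms_scores, reverse=True)

    @property
    def n_pred(self) -> int:
        return len(self.boxes)


@dataclass(frozen=True)
class ModelDifficultyParams:
    lambda1: float = 3.0
    lambda2: float = 3.0
    lambda3: float = 1.0
    clip_low: float = 0.5
    clip_high: float = 8.0

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("weights must be non-negative")
        if not self.clip_low < self.clip_high:
            raise ValueError("clip_low must be below clip_high")


def mean_confidence(summary: DetectionSummary) -> float:
    """p_bar for one slice (see module docstring)."""
    if summary.n_pred >= 1:
        return float(np.mean(summary.confidences))
    if not summary.pre_nms_scores:
        logger.warning(
            "slice %s: no post-NMS boxes and no pre-NMS scores; "
            "assuming worst-case p_bar = 0", summary.slice_id,
        )
        return 0.0
    top5 = list(summary.pre_nms_scores[:5])
    top5 += [0.0] * (5 - len(top5))
    return 1.0 - float(np.mean(top5))


def score_model(
    summary: DetectionSummary,
    params: ModelDifficultyParams = ModelDifficultyParams(),
) -> float:
    """Clipped model-driven difficulty for one slice."""
    p_bar = mean_confidence(summary)
    raw = (
        params.lambda1 * (1.0 - p_bar)
        + params.lambda2 * abs(summary.n_pred - summary.n_gt) / max(summary.n_gt, 1)
        + params.lambda3 * min(0.5 * summary.n_pred, 2.0)
    )
    return float(np.clip(raw, params.clip_low, params.clip_high))


def score_heldout(
    summaries: Sequence[DetectionSummary],
    heldout_patients: Iterable[str],
    slice_to_patient: Mapping[str, str],
    params: ModelDifficultyParams = ModelDifficultyParams(),
) -> pd.DataFrame:
    """Score a batch of slices, enforcing that every one belongs to the
    scoring held-out patient set (in-sample scoring is a leakage bug and
    is rejected with the offending patient IDs).

    Returns a DataFrame with columns ``slice_id``, ``p_bar``,
    ``c_det_raw``, ``c_det``.
    """
    heldout = set(heldout_patients)
    offending = sorted(
        {
            slice_to_patient[s.slice_id]
            for s in summaries
            if slice_to_patient.get(s.slice_id) not in heldout
        }
    )
    if offending:
        raise ValueError(
            "refusing to score slices outside the held-out scoring set; "
            f"offending patients: {', '.join(map(str, offending))}"
        )
    rows = []
    for s in summaries:
        p_bar = mean_confidence(s)
        raw = (
            params.lambda1 * (1.0 - p_bar)
            + params.lambda2 * abs(s.n_pred - s.n_gt) / max(s.n_gt, 1)
            + params.lambda3 * min(0.5 * s.n_pred, 2.0)
        )
        rows.append(
            {
                "slice_id": s.slice_id,
                "p_bar": p_bar,
                "c_det_raw": raw,
                "c_det": float(np.clip(raw, params.clip_low, params.clip_high)),
            }
        )
    return pd.DataFrame(rows, columns=["slice_id", "p_bar", "c_det_raw", "c_det"])
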