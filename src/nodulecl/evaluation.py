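"""Detection metrics from first principles: IoU, greedy one-to-one
matching, precision/recall, average precision as the exact area under
the monotone precision envelope, mAP50 and mAP50-95.

Conventions (recorded in every :class:`EvalResult`):

* matching is confidence-greedy with one-to-one ground-truth
  assignment — predictions are visited in descending confidence and
  each claims the unmatched ground-truth box of highest IoU, provided
  IoU >= tau;
* AP pools all slices (micro averaging) and integrates the monotone
  precision envelope exactly over every recall change-point — no
  11-point or 101-point sampling;
* the precision/recall operating point applies a confidence threshold
  (default 0.1) at IoU 0.5, whereas AP ranks the full prediction list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotations import Box

__all__ = [
    "MatchResult",
    "EvalResult",
    "IOU_GRID",
    "iou",
    "match",
    "precision_recall",
    "average_precision",
    "evaluate",
]

#: the mAP50-95 threshold grid {0.50, 0.55, ..., 0.95}
IOU_GRID = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))

Prediction = tuple[Box, float]


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes under the half-open pixel
    convention; 0 for disjoint boxes."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


@dataclass(frozen=True)
class MatchResult:
    """Per-prediction TP/FP labels (in descending-confidence order) and
    the unmatched ground-truth count, at one IoU threshold."""

    tp_flags: tuple[bool, ...]
    n_gt: int
    tau: float

    @property
    def tp(self) -> int:
        return sum(self.tp_flags)

    @property
    def fp(self) -> int:
        return len(self.tp_flags) - self.tp

    @property
    def fn(self) -> int:
        return self.n_gt - self.tp


def _sorted_by_confidence(predictions: Sequence[Prediction]) -> list[int]:
    # stable: ties keep input order
    return sorted(range(len(predictions)), key=lambda i: -predictions[i][1])


def match(
    predictions: Sequence[Prediction], gts: Sequence[Box], tau: float
) -> MatchResult:
    """Greedy one-to-one matching of one slice's predictions against its
    ground truth at IoU threshold ``tau``."""
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    order = _sorted_by_confidence(predictions)
    matched = [False] * len(gts)
    flags = []
    for i in order:
        box = predictions[i][0]
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if matched[j]:
                continue
            v = iou(box, gt)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= tau:
            matched[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    return MatchResult(tp_flags=tuple(flags), n_gt=len(gts), tau=tau)


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN); 0 on an empty
    denominator."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return precision, recall


def _pooled_flags(
    predictions: Mapping[str, Sequence[Prediction]],
    gts: Mapping[str, Sequence[Box]],
    tau: float,
) -> tuple[np.ndarray, int]:
    """TP flags for all predictions pooled across slices, sorted by
    descending confidence, matched greedily within each slice."""
    flat: list[tuple[float, str, int]] = []
    for slice_id, preds in predictions.items():
        for k, (_, conf) in enumerate(preds):
            flat.append((conf, slice_id, k))
    # descending confidence; ties broken by insertion order (stable)
    order = sorted(range(len(flat)), key=lambda i: -flat[i][0])
    matched = {s: [False] * len(g) for s, g in gts.items()}
    flags = np.zeros(len(flat), dtype=bool)
    for rank, i in enumerate(order):
        _, slice_id, k = flat[i]
        box = predictions[slice_id][k][0]
        slice_gts = gts.get(slice_id, ())
        taken = matched.setdefault(slice_id, [False] * len(slice_gts))
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(slice_gts):
            if taken[j]:
                continue
            v = iou(box, gt)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= tau:
            taken[best_j] = True
            flags[rank] = True
    n_gt = sum(len(g) for g in gts.values())
    return flags, n_gt


def average_precision(
    predictions: Mapping[str, Sequence[Prediction]],
    gts: Mapping[str, Sequence[Box]],
    tau: float,
) -> float:
    """AP at one IoU threshold: exact area under the monotone precision
    envelope of the pooled, confidence-ranked PR sweep.

    With no ground-truth boxes anywhere AP is undefined and reported as
    0 (the degenerate case is logged by :func:`evaluate`).
    """
    flags, n_gt = _pooled_flags(predictions, gts, tau)
    if n_gt == 0 or len(flags) == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # monotone (non-increasing) envelope from the right
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_recall = np.concatenate(([0.0], recall[:-1]))
    return float(np.sum((recall - prev_recall) * envelope))


@dataclass(frozen=True)
class EvalResult:
    """Detection metrics at the standard operating point plus the AP
    family, with the evaluator conventions recorded in ``metadata``."""

    precision: float
    recall: float
    tp: int
    fp: int
    fn: int
    ap_per_tau: dict[float, float]
    map50: float
    map50_95: float
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "ap_per_tau": {f"{t:.2f}": v for t, v in self.ap_per_tau.items()},
            "map50": self.map50,
            "map50_95": self.map50_95,
            "metadata": self.metadata,
        }


def evaluate(
    predictions: Mapping[str, Sequence[Prediction]],
    gts: Mapping[str, Sequence[Box]],
    confidence_threshold: float = 0.1,
    iou_threshold: float = 0.5,
) -> EvalResult:
    """Full evaluation: precision/recall at the (confidence, IoU)
    operating point — default 0.1 / 0.5 — and AP over the ten IoU
    thresholds of :data:`IOU_GRID`, whose mean is mAP50-95.

    ``predictions`` maps slice_id to (box, confidence) pairs and ``gts``
    maps slice_id to ground-truth boxes; slices absent from
    ``predictions`` count as having none.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError("iou_threshold must be in (0, 1]")
    if not 0.0 < confidence_threshold <= 1.0:
        raise ValueError("confidence_threshold must be in (0, 1]")
    # operating-point counts over all slices
    tp = fp = fn = 0
    all_slices = set(predictions) | set(gts)
    for slice_id in all_slices:
        preds = [
            p for p in predictions.get(slice_id, ())
            if p[1] >= confidence_threshold
        ]
        result = match(preds, gts.get(slice_id, ()), iou_threshold)
        tp += result.tp
        fp += result.fp
        fn += result.fn
    precision, recall = precision_recall(tp, fp, fn)

    ap_per_tau = {
        tau: average_precision(predictions, gts, tau) for tau in IOU_GRID
    }
    map50 = ap_per_tau[0.5]
    map50_95 = float(np.mean(list(ap_per_tau.values())))
    return EvalResult(
        precision=precision,
        recall=recall,
        tp=tp,
        fp=fp,
        fn=fn,
        ap_per_tau=ap_per_tau,
        map50=map50,
        map50_95=map50_95,
        metadata={
            "matching": "confidence-greedy one-to-one",
            "ap_integration": "exact all-point monotone envelope",
            "averaging": "micro (pooled over slices)",
            "confidence_threshold_applies_to": "precision/recall only",
            "confidence_threshold": confidence_threshold,
            "iou_threshold": iou_threshold,
        },
    )
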