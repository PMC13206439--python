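"""Difficulty fusion, tier assignment, and the three-stage progressive
curriculum.

The hybrid score is the convex combination

    c_hybrid = a * c_manual + (1 - a) * c_det,      a in [0, 1]

with a = 0.2 by default (a = 1 is a purely handcrafted curriculum,
a = 0 purely detector-driven).  Slices are tiered as simple
(c_hybrid <= 3), medium (3 < c_hybrid <= 6) or complex (c_hybrid > 6),
and stages grow cumulatively: stage 1 trains on simple positives plus
high-quality negatives, stage 2 adds medium positives and
medium-quality negatives, stage 3 covers the full training set.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DEFAULT_MIXING_COEFFICIENT",
    "TIERS",
    "StageConfig",
    "BaselineConfig",
    "CurriculumManifest",
    "fuse",
    "assign_tier",
    "default_stage_templates",
    "build_curriculum",
    "emit_baseline_config",
    "sweep_a",
]

logger = logging.getLogger(__name__)

DEFAULT_MIXING_COEFFICIENT = 0.2
TIERS = ("simple", "medium", "complex")
SIMPLE_MAX = 3.0
MEDIUM_MAX = 6.0


def fuse(c_manual, c_det, a: float = DEFAULT_MIXING_COEFFICIENT):
    """Convex combination of handcrafted and model-driven difficulty.

    Accepts scalars or aligned arrays; rejects a outside [0, 1].
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"mixing coefficient a={a} outside [0, 1]")
    c_manual = np.asarray(c_manual, dtype=float)
    c_det = np.asarray(c_det, dtype=float)
    out = a * c_manual + (1.0 - a) * c_det
    return float(out) if out.ndim == 0 else out


def assign_tier(c_hybrid: float) -> str:
    """Tier from the fused score: simple (<= 3), medium (3, 6], complex
    (> 6)."""
    if c_hybrid <= SIMPLE_MAX:
        return "simple"
    if c_hybrid <= MEDIUM_MAX:
        return "medium"
    return "complex"


@dataclass(frozen=True)
class StageConfig:
    """Training configuration for one curriculum stage.

    Loss weights are the (box, cls, dfl) triple consumed opaquely by the
    external YOLO-style trainer; augmentation is (rotation in degrees,
    translation fraction, scale fraction).
    """

    stage_index: int
    input_resolution: int
    epochs: int
    learning_rate: float
    loss_weights: tuple[float, float, float]
    augmentation: tuple[float, float, float]
    included_tiers: tuple[str, ...]
    included_negative_quality: tuple[str, ...]
    #: whether the stage continues from the previous stage's weights
    #: (the alternative being re-initialization); recorded for the
    #: external trainer, both options are representable
    init_from_previous: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("loss_weights", "augmentation", "included_tiers",
                  "included_negative_quality"):
            d[k] = list(d[k])
        return d


def default_stage_templates() -> list[StageConfig]:
    """The published three-stage schedule: resolutions 512/640/768,
    epochs 50/100/100, learning rates 3e-3/2e-3/1e-3, with per-stage
    loss weighting and augmentation strength."""
    return [
        StageConfig(
            stage_index=1, input_resolution=512, epochs=50, learning_rate=0.003,
            loss_weights=(2.0, 4.0, 0.1), augmentation=(3.0, 0.05, 0.10),
            included_tiers=("simple",), included_negative_quality=("high",),
        ),
        StageConfig(
            stage_index=2, input_resolution=640, epochs=100, learning_rate=0.002,
            loss_weights=(5.0, 2.0, 0.5), augmentation=(8.0, 0.10, 0.20),
            included_tiers=("simple", "medium"),
            included_negative_quality=("high", "medium"),
        ),
        StageConfig(
            stage_index=3, input_resolution=768, epochs=100, learning_rate=0.001,
            loss_weights=(7.0, 1.5, 1.0), augmentation=(12.0, 0.15, 0.30),
            included_tiers=("simple", "medium", "complex"),
            included_negative_quality=("high", "medium", "low"),
        ),
    ]


@dataclass(frozen=True)
class BaselineConfig:
    """Single-stage training configuration without curriculum
    scheduling (uniformly shuffled data)."""

    input_resolution: int = 640
    batch_size: int = 32
    max_epochs: int = 500
    learning_rate: float = 1e-4
    momentum: float = 0.937
    weight_decay: float = 5e-4
    patience: int = 30
    loss_weights: tuple[float, float, float] = (5.0, 2.0, 0.3)
    confidence_threshold: float = 0.1
    iou_threshold: float = 0.5

    def to_dict(self) -> dict:
        d = asdict(self)
        d["loss_weights"] = list(d["loss_weights"])
        return d


def emit_baseline_config() -> BaselineConfig:
    """The no-curriculum baseline configuration."""
    return BaselineConfig()


@dataclass
class CurriculumManifest:
    """Per-stage sample lists plus the provenance needed to reproduce
    them.  Stage sample sets are nested and stage 3 covers the full
    training set."""

    stages: list[dict]  # each: {"positives": [...], "negatives": [...]}
    provenance: dict = field(default_factory=dict)

    def stage_ids(self, stage_index: int) -> list[str]:
        s = self.stages[stage_index - 1]
        return sorted(s["positives"]) + sorted(s["negatives"])

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "stages": [
                {
                    "stage_index": i + 1,
                    "positives": sorted(s["positives"]),
                    "negatives": sorted(s["negatives"]),
                }
                for i, s in enumerate(self.stages)
            ],
            "provenance": self.provenance,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CurriculumManifest":
        payload = yaml.safe_load(Path(path).read_text())
        stages = [
            {"positives": list(s["positives"]), "negatives": list(s["negatives"])}
            for s in sorted(payload["stages"], key=lambda s: s["stage_index"])
        ]
        return cls(stages=stages, provenance=payload.get("provenance", {}))


def _validate_scores(scores: pd.DataFrame, required: Sequence[str]) -> None:
    missing = [c for c in required if c not in scores.columns]
    if missing:
        raise ValueError(f"scores table is missing columns: {missing}")


def build_curriculum(
    scores: pd.DataFrame,
    stage_templates: Sequence[StageConfig] | None = None,
    provenance: Mapping | None = None,
) -> tuple[CurriculumManifest, list[StageConfig]]:
    """Assemble the three-stage curriculum from a per-slice score table.

    ``scores`` needs columns ``slice_id``, ``tier`` (positives' hybrid
    tier), ``is_positive`` (bool) and ``quality_tier`` (negatives'
    image-quality tier).  Positives are staged by difficulty tier,
    negatives by quality tier; stages are cumulative, so the manifests
    are nested and stage 3 equals the full set.
    """
    _validate_scores(scores, ("slice_id", "tier", "is_positive", "quality_tier"))
    if scores["slice_id"].duplicated().any():
        raise ValueError("duplicate slice_id in scores table")
    templates = list(stage_templates or default_stage_templates())

    pos = scores[scores["is_positive"].astype(bool)]
    neg = scores[~scores["is_positive"].astype(bool)]
    if not (pos["tier"] == "simple").any():
        logger.warning(
            "no simple-tier positives: stage 1 would train on negatives only"
        )

    stages = []
    for template in templates:
        stages.append(
            {
                "positives": pos.loc[
                    pos["tier"].isin(template.included_tiers), "slice_id"
                ].tolist(),
                "negatives": neg.loc[
                    neg["quality_tier"].isin(template.included_negative_quality),
                    "slice_id",
                ].tolist(),
            }
        )
    # stage 3 covers everything regardless of unknown tier labels
    stages[-1] = {
        "positives": pos["slice_id"].tolist(),
        "negatives": neg["slice_id"].tolist(),
    }
    manifest = CurriculumManifest(
        stages=stages, provenance=dict(provenance or {})
    )
    return manifest, templates


def sweep_a(
    scores: pd.DataFrame,
    a_grid: Iterable[float],
    stage_templates: Sequence[StageConfig] | None = None,
) -> dict[float, dict]:
    """Build one curriculum per mixing coefficient.

    ``scores`` needs columns ``slice_id``, ``c_manual``, ``c_det``,
    ``is_positive``, ``quality_tier``.  Returns, per deduplicated ``a``,
    the manifest and the tier-occupancy counts.
    """
    _validate_scores(
        scores, ("slice_id", "c_manual", "c_det", "is_positive", "quality_tier")
    )
    out: dict[float, dict] = {}
    for a in sorted(set(float(a) for a in a_grid)):
        c_hybrid = fuse(scores["c_manual"].to_numpy(),
                        scores["c_det"].to_numpy(), a)
        table = scores.assign(
            c_hybrid=c_hybrid,
            tier=[assign_tier(c) for c in np.atleast_1d(c_hybrid)],
        )
        manifest, _ = build_curriculum(
            table, stage_templates, provenance={"a": a}
        )
        tier_counts = (
            table.loc[table["is_positive"].astype(bool), "tier"]
            .value_counts()
            .reindex(TIERS, fill_value=0)
            .to_dict()
        )
        out[a] = {"manifest": manifest, "tier_counts": tier_counts}
    return out
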