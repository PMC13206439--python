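"""On-disk interchange: dataset directories (PNG images and masks,
YOLO-format labels, a YAML manifest with the patient-slice mapping and
pixel spacing) and detector-prediction JSON files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from PIL import Image

from .annotations import Box, Nodule, SliceRecord, read_labels, write_labels
from .modeldriven import DetectionSummary

__all__ = [
    "write_dataset",
    "load_dataset",
    "write_predictions",
    "read_predictions",
]

MANIFEST_NAME = "manifest.yaml"


def write_dataset(
    records: Sequence[SliceRecord],
    out_dir: str | Path,
    provenance: dict | None = None,
) -> Path:
    """Materialize records as a dataset directory:

    ``images/<slice_id>.png``, ``masks/<slice_id>.png`` (binary, when a
    mask exists), ``labels/<slice_id>.txt`` (YOLO format), and a
    ``manifest.yaml`` mapping patients to slices with per-slice spacing.
    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    for sub in ("images", "masks", "labels"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    patients: dict[str, list[dict]] = {}
    for record in records:
        if record.image is None:
            raise ValueError(f"slice {record.slice_id} has no image to write")
        img_rel = f"images/{record.slice_id}.png"
        Image.fromarray(np.asarray(record.image, dtype=np.uint8)).save(
            out_dir / img_rel
        )
        entry: dict = {
            "slice_id": record.slice_id,
            "image": img_rel,
            "spacing_mm": float(record.spacing_mm),
        }
        if record.mask is not None:
            mask_rel = f"masks/{record.slice_id}.png"
            Image.fromarray(
                (np.asarray(record.mask) > 0).astype(np.uint8) * 255
            ).save(out_dir / mask_rel)
            entry["mask"] = mask_rel
        label_rel = f"labels/{record.slice_id}.txt"
        h, w = np.asarray(record.image).shape[:2]
        write_labels([n.box for n in record.nodules], (w, h), out_dir / label_rel)
        entry["label"] = label_rel
        entry["areas_px"] = [float(n.area_px) for n in record.nodules]
        patients.setdefault(record.patient_id, []).append(entry)
    manifest = {
        "patients": patients,
        "provenance": provenance or {},
    }
    path = out_dir / MANIFEST_NAME
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


def load_dataset(manifest_path: str | Path, load_images: bool = True) -> list[SliceRecord]:
    """Load a dataset directory back into records (inverse of
    :func:`write_dataset`)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = yaml.safe_load(manifest_path.read_text())
    records: list[SliceRecord] = []
    for patient_id in sorted(manifest["patients"]):
        for entry in manifest["patients"][patient_id]:
            image = None
            size = None
            if load_images:
                image = np.asarray(Image.open(root / entry["image"]))
                size = (image.shape[1], image.shape[0])
            mask = None
            if entry.get("mask"):
                mask = (np.asarray(Image.open(root / entry["mask"])) > 0).astype(
                    np.uint8
                )
                size = size or (mask.shape[1], mask.shape[0])
            if size is None:
                with Image.open(root / entry["image"]) as im:
                    size = im.size
            boxes = read_labels(root / entry["label"], size)
            areas = entry.get("areas_px") or [None] * len(boxes)
            if len(areas) != len(boxes):
                raise ValueError(
                    f"{manifest_path}: slice {entry['slice_id']}: "
                    f"{len(areas)} recorded areas for {len(boxes)} boxes"
                )
            nodules = [
                Nodule.from_box(b, area_px=a) for b, a in zip(boxes, areas)
            ]
            records.append(
                SliceRecord(
                    patient_id=patient_id,
                    slice_id=entry["slice_id"],
                    image=image,
                    spacing_mm=float(entry["spacing_mm"]),
                    nodules=nodules,
                    mask=mask,
                )
            )
    return records


def write_predictions(
    summaries: Sequence[DetectionSummary], path: str | Path
) -> None:
    """Write detector summaries as a JSON list of per-slice records
    (slice_id, boxes as [x_min, y_min, x_max, y_max], confidences,
    pre_nms_scores, n_gt)."""
    payload = [
        {
            "slice_id": s.slice_id,
            "boxes": [list(b.as_tuple()) for b in s.boxes],
            "confidences": list(s.confidences),
            "pre_nms_scores": list(s.pre_nms_scores),
            "n_gt": s.n_gt,
        }
        for s in summaries
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_predictions(path: str | Path) -> list[DetectionSummary]:
    """Read a prediction JSON file back into summaries."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid JSON ({exc})") from None
    summaries = []
    for i, rec in enumerate(payload):
        for key in ("slice_id", "boxes", "confidences"):
            if key not in rec:
                raise ValueError(f"{path}: record {i} is missing field {key!r}")
        summaries.append(
            DetectionSummary(
                slice_id=rec["slice_id"],
                boxes=[Box(*b) for b in rec["boxes"]],
                confidences=[float(c) for c in rec["confidences"]],
                n_gt=int(rec.get("n_gt", 0)),
                pre_nms_scores=[float(s) for s in rec.get("pre_nms_scores", [])],
            )
        )
    return summaries
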