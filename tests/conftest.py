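import numpy as np
import pytest

from nodulecl import (
    Box,
    FixtureSpec,
    Nodule,
    QualityMetrics,
    SliceRecord,
    compute_quality,
    generate_dataset,
)


def make_record(
    patient_id="P0",
    slice_id="P0_S0",
    nodules=(),
    quality_tier=None,
    spacing_mm=0.7,
    image=None,
):
    """Lightweight record for tests that don't need a real raster."""
    record = SliceRecord(
        patient_id=patient_id,
        slice_id=slice_id,
        image=image,
        spacing_mm=spacing_mm,
        nodules=list(nodules),
    )
    if quality_tier is not None:
        record.quality = QualityMetrics(
            lung_coverage=1.0,
            intensity_heterogeneity=20.0,
            laplacian_variance={"high": 800.0, "medium": 300.0, "low": 50.0}[
                quality_tier
            ],
            contrast={"high": 45.0, "medium": 20.0, "low": 5.0}[quality_tier],
            quality_tier=quality_tier,
        )
    return record


def make_nodule(area_px=500.0, aspect_ratio=1.2, x=10.0, y=10.0):
    w = np.sqrt(area_px * aspect_ratio)
    h = area_px / w
    return Nodule(
        box=Box(x, y, x + w, y + h), area_px=area_px, aspect_ratio=aspect_ratio
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Default-condition synthetic dataset with quality computed."""
    records = generate_dataset(FixtureSpec(seed=7))
    for r in records:
        compute_quality(r)
    return records


@pytest.fixture(scope="session")
def small_dataset():
    """Small, fast dataset for I/O and pipeline tests."""
    spec = FixtureSpec(n_patients=4, slices_per_patient=3, image_size=160, seed=11)
    records = generate_dataset(spec)
    for r in records:
        compute_quality(r)
    return records
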