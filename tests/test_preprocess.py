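import logging

import numpy as np
import pytest

from nodulecl import (
    Box,
    FixtureSpec,
    Nodule,
    SliceRecord,
    apply_clahe,
    compute_quality,
    filter_small_nodules,
    fixed_size_subset,
    generate_dataset,
    pad_resize,
    proportional_subsets,
    sample_slices,
    split_patients,
    teacher_split,
)
from tests.conftest import make_nodule, make_record


class TestComputeQuality:
    def test_constant_image_is_low_tier(self):
        r = make_record(image=np.full((64, 64), 128, dtype=np.uint8))
        q = compute_quality(r)
        assert q.laplacian_variance == 0
        assert q.contrast == 0
        assert q.quality_tier == "low"

    def test_sharp_high_contrast_fixture_is_high_tier(self):
        records = generate_dataset(
            FixtureSpec(
                n_patients=1, slices_per_patient=2, image_size=256, seed=2,
                blur_sigma_range=(0.0, 0.0), contrast_range=(60.0, 70.0),
            )
        )
        for r in records:
            q = compute_quality(r)
            assert q.laplacian_variance > 500
            assert q.contrast > 30
            assert q.quality_tier == "high"

    def test_lung_coverage_is_mask_fraction(self):
        r = make_record(image=np.zeros((8, 8), dtype=np.uint8))
        r.lung_mask = np.zeros((8, 8), dtype=np.uint8)
        r.lung_mask[:4, :4] = 1  # 25% of pixels
        assert compute_quality(r).lung_coverage == 0.25

    def test_metrics_stored_on_record(self):
        r = make_record(image=np.zeros((8, 8), dtype=np.uint8))
        q = compute_quality(r)
        assert r.quality is q


class TestClahe:
    def test_constant_image_unchanged(self):
        img = np.full((64, 64), 77, dtype=np.uint8)
        np.testing.assert_array_equal(apply_clahe(img), img)

    def test_contrast_increases_on_low_contrast_fixture(self):
        records = generate_dataset(
            FixtureSpec(
                n_patients=1, slices_per_patient=3, image_size=256, seed=4,
                contrast_range=(8.0, 12.0),
            )
        )
        for r in records:
            before = compute_quality(r).contrast
            r.image = apply_clahe(r.image)
            after = compute_quality(r).contrast
            assert after > before

    def test_closure_on_repeated_application(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (64, 64), dtype=np.uint8)
        once = apply_clahe(img)
        twice = apply_clahe(once)
        for out in (once, twice):
            assert out.dtype == np.uint8
            assert out.shape == img.shape


class TestPadResize:
    def test_identity_when_already_target(self):
        records = generate_dataset(
            FixtureSpec(n_patients=1, slices_per_patient=1, image_size=128,
                        seed=1, nodule_count_distribution={2: 1.0})
        )
        r = records[0]
        out, tfm = pad_resize(r, 128)
        np.testing.assert_array_equal(out.image, r.image)
        assert tfm.scale == 1.0 and tfm.pad_x == 0 and tfm.pad_y == 0
        for a, b in zip(out.boxes, r.boxes):
            assert a.as_tuple() == b.as_tuple()

    def test_landscape_input_is_centred_with_symmetric_padding(self):
        r = make_record(image=np.full((200, 400), 100, dtype=np.uint8))
        out, tfm = pad_resize(r, 512)
        assert tfm.scale == pytest.approx(1.28)
        assert out.image.shape == (512, 512)
        # content spans the full width, 256 rows centred vertically
        assert tfm.pad_x == 0
        assert tfm.pad_y == 128
        assert (out.image[128:384, :] > 0).all()
        assert (out.image[:128, :] == 0).all()
        assert (out.image[384:, :] == 0).all()

    def test_box_round_trip_within_half_pixel(self):
        rng = np.random.default_rng(6)
        r = make_record(image=np.zeros((300, 180), dtype=np.uint8))
        _, tfm = pad_resize(r, 512)
        for _ in range(500):
            x0, y0 = rng.uniform(0, 178), rng.uniform(0, 298)
            box = Box(x0, y0, rng.uniform(x0 + 1, 180), rng.uniform(y0 + 1, 300))
            back = tfm.invert_box(tfm.apply_box(box))
            assert max(
                abs(a - b) for a, b in zip(box.as_tuple(), back.as_tuple())
            ) < 0.5

    def test_spacing_and_area_rescaled(self):
        r = make_record(
            image=np.zeros((256, 256), dtype=np.uint8),
            nodules=[make_nodule(area_px=400.0)],
            spacing_mm=0.7,
        )
        out, _ = pad_resize(r, 512)
        assert out.spacing_mm == pytest.approx(0.35)
        assert out.nodules[0].area_px == pytest.approx(1600.0)


class TestFilterSmallNodules:
    def test_sub_threshold_nodule_removed_slice_kept(self):
        # 4x4 px at 0.7 mm/px = 2.8 mm < 3 mm
        r = make_record(nodules=[Nodule.from_box(Box(0, 0, 4, 4))], spacing_mm=0.7)
        out = filter_small_nodules([r])
        assert len(out) == 1
        assert out[0].nodules == []

    def test_exact_threshold_retained(self):
        r = make_record(nodules=[Nodule.from_box(Box(0, 0, 3, 3))], spacing_mm=1.0)
        assert len(filter_small_nodules([r])[0].nodules) == 1

    def test_empty_dataset_unchanged(self):
        r = make_record()
        assert filter_small_nodules([r])[0].nodules == []

    def test_idempotent(self):
        records = [
            make_record(
                slice_id=f"s{i}",
                nodules=[Nodule.from_box(Box(0, 0, 3 + i, 3 + i))],
                spacing_mm=0.7,
            )
            for i in range(5)
        ]
        once = filter_small_nodules(records)
        twice = filter_small_nodules(once)
        assert [len(r.nodules) for r in once] == [len(r.nodules) for r in twice]

    def test_missing_spacing_rejected(self):
        r = make_record(nodules=[make_nodule()])
        r.spacing_mm = None
        with pytest.raises(ValueError, match="spacing"):
            filter_small_nodules([r])


def _sampling_records(n_pos, n_neg):
    records = [
        make_record(
            patient_id=f"P{i % 10}", slice_id=f"pos{i}",
            nodules=[make_nodule()], quality_tier="medium",
        )
        for i in range(n_pos)
    ]
    tiers = ("high", "medium", "low")
    records += [
        make_record(
            patient_id=f"P{i % 10}", slice_id=f"neg{i}",
            quality_tier=tiers[i % 3],
        )
        for i in range(n_neg)
    ]
    return records


class TestSampleSlices:
    def test_published_one_to_two_ratio(self):
        out = sample_slices(_sampling_records(100, 1000), ratio=2.0, seed=0)
        positives = [r for r in out if r.has_nodule]
        negatives = [r for r in out if not r.has_nodule]
        assert len(positives) == 100
        assert len(negatives) == 200

    def test_all_nodule_slices_always_retained(self):
        records = _sampling_records(30, 300)
        out = sample_slices(records, ratio=2.0, seed=1)
        assert {r.slice_id for r in out if r.has_nodule} == {
            r.slice_id for r in records if r.has_nodule
        }

    def test_negatives_chosen_best_quality_first(self):
        out = sample_slices(_sampling_records(10, 90), ratio=2.0, seed=0)
        chosen = [r.quality.quality_tier for r in out if not r.has_nodule]
        # 30 high-quality negatives exist, and 20 are wanted
        assert chosen.count("high") == 20

    def test_capped_when_too_few_negatives(self, caplog):
        with caplog.at_level(logging.WARNING, logger="nodulecl.preprocess"):
            out = sample_slices(_sampling_records(100, 50), ratio=2.0, seed=0)
        assert len(out) == 150
        assert any("keeping all" in m for m in caplog.messages)

    def test_no_positives_keeps_nothing(self):
        assert sample_slices(_sampling_records(0, 40), ratio=2.0, seed=0) == []

    def test_missing_quality_rejected(self):
        with pytest.raises(ValueError, match="quality"):
            sample_slices([make_record()], seed=0)


def _patient_records(slice_counts):
    records = []
    for i, count in enumerate(slice_counts):
        pid = f"P{i:03d}"
        records += [
            make_record(patient_id=pid, slice_id=f"{pid}_s{j}")
            for j in range(count)
        ]
    return records


class TestSplitPatients:
    def test_ten_equal_patients_split_8_1_1(self):
        records = _patient_records([5] * 10)
        split = split_patients(records, seed=0)
        assert len(split.patients("train")) == 8
        assert len(split.patients("val")) == 1
        assert len(split.patients("test")) == 1

    def test_deterministic_and_seed_sensitive(self):
        records = _patient_records([3] * 20)
        a = split_patients(records, seed=5)
        b = split_patients(records, seed=5)
        c = split_patients(records, seed=6)
        assert a.assignment == b.assignment
        assert a.assignment != c.assignment

    def test_partition_property(self):
        records = _patient_records([1, 7, 3, 9, 2, 5, 4, 6, 8, 2, 3])
        split = split_patients(records, seed=2)
        all_patients = {r.patient_id for r in records}
        subsets = [set(split.patients(s)) for s in ("train", "val", "test")]
        assert set.union(*subsets) == all_patients
        assert sum(len(s) for s in subsets) == len(all_patients)

    def test_slice_fractions_near_targets(self):
        rng = np.random.default_rng(0)
        records = _patient_records(list(rng.integers(5, 25, size=100)))
        split = split_patients(records, seed=3)
        total = len(records)
        for subset, target in zip(("train", "val", "test"), (0.8, 0.1, 0.1)):
            frac = len(split.select(records, subset)) / total
            assert abs(frac - target) <= 0.03

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="patients"):
            split_patients(_patient_records([4, 4]), seed=0)


class TestTeacherSplit:
    def test_hundred_equal_patients_split_72_8_20(self):
        records = _patient_records([10] * 100)
        t_train, t_val, heldout = teacher_split(records, seed=1)
        assert len({r.patient_id for r in t_train}) == 72
        assert len({r.patient_id for r in t_val}) == 8
        assert len({r.patient_id for r in heldout}) == 20

    def test_patient_disjointness(self):
        records = _patient_records([3, 5, 2, 8, 4, 7, 1, 6, 9, 2] * 3)
        parts = teacher_split(records, seed=2)
        patient_sets = [{r.patient_id for r in p} for p in parts]
        assert not (patient_sets[0] & patient_sets[1])
        assert not (patient_sets[0] & patient_sets[2])
        assert not (patient_sets[1] & patient_sets[2])

    def test_deterministic(self):
        records = _patient_records([4] * 25)
        a = teacher_split(records, seed=9)
        b = teacher_split(records, seed=9)
        for pa, pb in zip(a, b):
            assert [r.slice_id for r in pa] == [r.slice_id for r in pb]


class TestProportionalSubsets:
    def test_full_fraction_returns_everything(self):
        records = _patient_records([4] * 10)
        for fold in proportional_subsets(records, 1.0, n_folds=3, seed=0):
            assert len(fold) == len(records)

    def test_half_fraction_on_uniform_patients(self):
        records = _patient_records([10] * 100)  # 1000 slices
        for fold in proportional_subsets(records, 0.5, n_folds=3, seed=1):
            assert 475 <= len(fold) <= 525

    def test_fraction_tolerance_on_uneven_patients(self):
        rng = np.random.default_rng(4)
        records = _patient_records(list(rng.integers(3, 30, size=80)))
        total = len(records)
        for fraction in (0.5, 0.2, 0.1):
            for fold in proportional_subsets(records, fraction, n_folds=3, seed=2):
                assert abs(len(fold) / total - fraction) <= 0.05

    def test_patient_atomicity(self):
        records = _patient_records([6] * 30)
        by_patient = {}
        for r in records:
            by_patient.setdefault(r.patient_id, []).append(r.slice_id)
        for fold in proportional_subsets(records, 0.2, n_folds=2, seed=3):
            included = {r.patient_id for r in fold}
            fold_ids = {r.slice_id for r in fold}
            for pid in included:
                assert set(by_patient[pid]) <= fold_ids

    def test_folds_differ(self):
        records = _patient_records([5] * 40)
        folds = proportional_subsets(records, 0.5, n_folds=3, seed=5)
        ids = [frozenset(r.slice_id for r in f) for f in folds]
        assert len(set(ids)) > 1

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            proportional_subsets(_patient_records([3] * 5), 0.0)


class TestFixedSizeSubset:
    def test_stop_rule_includes_boundary_patient_whole(self):
        records = _patient_records([3, 3, 3])
        out = fixed_size_subset(records, 5, seed=42)
        assert len(out) == 6
        assert len({r.patient_id for r in out}) == 2

    def test_target_equal_total_includes_all(self):
        records = _patient_records([3, 4, 5])
        assert len(fixed_size_subset(records, 12, seed=42)) == 12

    def test_deterministic(self):
        records = _patient_records([4] * 30)
        a = fixed_size_subset(records, 50, seed=42)
        b = fixed_size_subset(records, 50, seed=42)
        assert [r.slice_id for r in a] == [r.slice_id for r in b]

    def test_oversized_target_rejected(self):
        with pytest.raises(ValueError, match="only"):
            fixed_size_subset(_patient_records([2, 2]), 10, seed=42)
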