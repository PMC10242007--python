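import numpy as np
import pytest

from fedglioma.preprocess import (SliceDataset, attenuate_outside_mask,
                                  augment, extract_tumor_slices,
                                  preprocess_cohort, preprocess_scan,
                                  resize_normalize)
from fedglioma.synthetic import PatientScan


def make_scan(mask, label=1):
    vol = np.random.default_rng(0).random(mask.shape)
    return PatientScan("p0", "s", label,
                       {"FLAIR": vol, "T1ce": 0.5 * vol}, mask)


class TestExtraction:
    def test_fifteen_records_per_patient(self, small_site_scans):
        for scan in small_site_scans:
            records = extract_tumor_slices(scan, n_per_view=5)
            assert len(records) == 15
            views = {r.view for r in records}
            assert views == {"axial", "sagittal", "coronal"}
            for r in records:
                assert r.mask.sum() > 0
                assert r.label == scan.label

    def test_slice_count_identity_over_cohort(self, small_site_scans):
        total = sum(len(extract_tumor_slices(s)) for s in small_site_scans)
        assert total == 15 * len(small_site_scans)

    def test_largest_area_selection_with_tie_break(self):
        # per-slice areas along axis 0: [3, 5, 4, 5, 2, 1]
        mask = np.zeros((6, 8, 8), dtype=bool)
        for idx, area in enumerate([3, 5, 4, 5, 2, 1]):
            mask[idx].flat[:area] = True
        mask[:, -5:, -5:] = True   # satisfy the other two axes
        areas = mask.sum(axis=(1, 2))
        scan = make_scan(mask)
        records = [r for r in extract_tumor_slices(scan, n_per_view=5)
                   if r.view == "axial"]
        picked = [r.slice_index for r in records]
        order = np.argsort(-areas, kind="stable")[:5]
        assert picked == list(order)
        assert picked[:2] == [1, 3]   # the two area-5 slices, low index first

    def test_exactly_five_candidate_slices_all_selected(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[2:7, 2:7, 2:7] = True
        records = [r for r in extract_tumor_slices(make_scan(mask))
                   if r.view == "axial"]
        assert sorted(r.slice_index for r in records) == [2, 3, 4, 5, 6]

    def test_insufficient_slices_names_axis(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[2:5, 2:7, 2:7] = True   # only 3 slices along axial
        with pytest.raises(ValueError, match="axial"):
            extract_tumor_slices(make_scan(mask))


class TestAttenuation:
    def test_outside_reduced_to_one_third(self):
        img = np.full((4, 4), 0.9)
        mask = np.zeros((4, 4), bool)
        out = attenuate_outside_mask(img, mask)
        assert np.allclose(out, 0.3)

    def test_inside_unchanged_and_full_mask_identity(self):
        img = np.full((4, 4), 0.9)
        assert np.allclose(attenuate_outside_mask(img, np.ones((4, 4))), 0.9)

    def test_applied_twice_compounds_to_one_ninth(self):
        img = np.ones((3, 3))
        mask = np.zeros((3, 3), bool)
        twice = attenuate_outside_mask(attenuate_outside_mask(img, mask),
                                       mask)
        assert np.allclose(twice, 1.0 / 9.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            attenuate_outside_mask(np.ones((4, 4)), np.ones((5, 5)))


class TestResizeNormalize:
    def test_constant_input_maps_to_zeros(self):
        out = resize_normalize(np.full((10, 12), 0.7), out_size=8)
        assert out.shape == (8, 8)
        assert np.allclose(out, 0.0)

    def test_minmax_contract(self):
        rng = np.random.default_rng(2)
        out = resize_normalize(rng.random((16, 16)), out_size=16)
        assert out.min() == pytest.approx(0.0)
        assert out.max() == pytest.approx(1.0)

    def test_hand_minmax_without_resampling(self):
        out = resize_normalize(np.array([[1.0, 3.0], [3.0, 5.0]]),
                               out_size=2)
        assert np.allclose(out, [[0.0, 0.5], [0.5, 1.0]])

    def test_output_within_unit_interval_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            h, w = rng.integers(5, 40, 2)
            img = rng.normal(0, 10, (2, h, w))
            out = resize_normalize(img, out_size=16)
            assert out.shape == (2, 16, 16)
            assert out.min() >= 0.0 and out.max() <= 1.0


class _NoFlipRng:
    """Forces the no-flip branch and a fixed rotation angle."""

    def __init__(self, angle):
        self.angle = angle

    def random(self):
        return 0.9

    def uniform(self, lo, hi):
        return self.angle


class TestAugmentation:
    def test_identity_draw(self):
        img = np.random.default_rng(0).random((2, 16, 16))
        assert np.allclose(augment(img, _NoFlipRng(0.0)), img)

    def test_flip_is_an_involution_at_zero_angle(self):
        class FlipRng(_NoFlipRng):
            def random(self):
                return 0.1
        img = np.random.default_rng(0).random((2, 16, 16))
        twice = augment(augment(img, FlipRng(0.0)), FlipRng(0.0))
        assert np.allclose(twice, img)

    def test_angle_bounded_by_ten_degrees(self):
        rng = np.random.default_rng(5)
        drawn = []

        class SpyRng:
            def random(self):
                return rng.random()

            def uniform(self, lo, hi):
                a = rng.uniform(lo, hi)
                drawn.append(a)
                return a

        img = np.random.default_rng(0).random((2, 16, 16))
        for _ in range(50):
            out = augment(img, SpyRng())
            assert out.min() >= 0.0 and out.max() <= 1.0
        assert max(abs(a) for a in drawn) <= 10.0


class TestPipelineAndContainer:
    def test_preprocess_scan_output_contract(self, small_site_scans):
        records = preprocess_scan(small_site_scans[0], out_size=32)
        assert len(records) == 15
        for r in records:
            assert r.image.shape == (2, 32, 32)
            assert r.image.min() >= 0.0 and r.image.max() <= 1.0
            assert r.mask is None

    def test_dataset_hdf5_roundtrip(self, tmp_path, small_slice_dataset):
        path = tmp_path / "slices.h5"
        small_slice_dataset.to_hdf5(path)
        assert (tmp_path / "slices.csv").exists()
        back = SliceDataset.from_hdf5(path)
        assert len(back) == len(small_slice_dataset)
        assert np.allclose(back.images, small_slice_dataset.images,
                           atol=1e-6)
        assert np.array_equal(back.labels, small_slice_dataset.labels)
        assert list(back.patient_ids) == \
            list(small_slice_dataset.patient_ids)

    def test_cohort_slice_count(self, small_site_scans,
                                small_slice_dataset):
        assert len(small_slice_dataset) == 15 * len(small_site_scans)
        assert small_slice_dataset.n_patients == len(small_site_scans)
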