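"""Otsu thresholding, per-well threshold propagation, labeling and areas."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from conftest import draw_disk, otsu_scan_oracle
from h2axquant.io import FieldImage, FieldImageRef
from h2axquant.segmentation import (
    ConstantImageError,
    LabeledMask,
    ThresholdPolicy,
    exclude_edge_objects,
    object_areas,
    otsu_threshold,
    segment_well,
)


def _field(pixels, position="0001", bit_depth=16, calibration=1.0):
    ref = FieldImageRef(channel="DAPI", date_token="20230101", well="B8",
                        position=position, acq_run="01")
    return FieldImage(pixels=np.asarray(pixels), bit_depth=bit_depth,
                      calibration=calibration, ref=ref)


class TestOtsuThreshold:
    def test_two_class_separation(self, rng):
        values = np.full(1000, 10, dtype=np.uint16)
        values[:100] = 200
        rng.shuffle(values)
        image = values.reshape(25, 40)
        t = otsu_threshold(image)
        assert 10 <= t < 200
        assert (image > t).mean() == pytest.approx(0.10)

    def test_constant_image_raises(self):
        with pytest.raises(ConstantImageError):
            otsu_threshold(np.full((8, 8), 500, dtype=np.uint16))

    @pytest.mark.parametrize("dtype", [np.uint8, np.uint16])
    def test_matches_exhaustive_scan_on_random_images(self, dtype, rng):
        hi = 255 if dtype == np.uint8 else 40000
        for _ in range(25):
            image = rng.integers(0, hi, size=(32, 32)).astype(dtype)
            assert otsu_threshold(image) == otsu_scan_oracle(image)

    @given(
        hnp.arrays(
            dtype=np.uint16,
            shape=(6, 6),
            elements=st.integers(min_value=0, max_value=5000),
        )
    )
    @settings(max_examples=50)
    def test_oracle_equivalence_property(self, image):
        if image.min() == image.max():
            with pytest.raises(ConstantImageError):
                otsu_threshold(image)
        else:
            assert otsu_threshold(image) == otsu_scan_oracle(image)

    def test_shift_equivariance(self, rng):
        image = rng.integers(0, 1000, size=(32, 32)).astype(np.uint16)
        shift = 500
        t = otsu_threshold(image)
        t_shifted = otsu_threshold(image + shift)
        assert t_shifted == t + shift
        np.testing.assert_array_equal(image > t, (image + shift) > t_shifted)

    def test_agrees_with_skimage_on_bimodal_uint8(self, rng):
        from skimage.filters import threshold_otsu

        image = np.where(
            rng.random((64, 64)) < 0.3,
            rng.integers(180, 256, (64, 64)),
            rng.integers(0, 60, (64, 64)),
        ).astype(np.uint8)
        ours = otsu_threshold(image)
        theirs = threshold_otsu(image)
        np.testing.assert_array_equal(image > ours, image > theirs)


class TestSegmentWell:
    def _well(self, rng, n_fields=4):
        fields = []
        for i in range(n_fields):
            img = rng.integers(0, 50 + 40 * i, (64, 64)).astype(np.uint16)
            draw_disk(img, 20 + 3 * i, 20, 8, 2000 + 300 * i)
            fields.append(_field(img, position=f"{i+1:04d}"))
        return fields

    def test_first_field_threshold_propagates(self, rng):
        fields = self._well(rng)
        individual = [otsu_threshold(f) for f in fields]
        assert len(set(individual)) > 1  # fields genuinely differ
        masks = segment_well(fields, ThresholdPolicy("per_well_first_field"))
        assert all(m.threshold_used == individual[0] for m in masks)

    def test_single_field_matches_per_image(self, rng):
        fields = self._well(rng, n_fields=1)
        a = segment_well(fields, ThresholdPolicy("per_well_first_field"))
        b = segment_well(fields, ThresholdPolicy("per_image"))
        assert a[0].threshold_used == b[0].threshold_used
        np.testing.assert_array_equal(a[0].labels, b[0].labels)

    def test_pooled_mode_uses_one_threshold(self, rng):
        fields = self._well(rng)
        masks = segment_well(fields, ThresholdPolicy("per_well_pooled"))
        assert len({m.threshold_used for m in masks}) == 1

    def test_recovers_planted_disk_count(self):
        image = np.zeros((128, 128), dtype=np.uint16)
        for cx, cy in [(20, 20), (60, 40), (100, 90), (30, 100)]:
            draw_disk(image, cx, cy, 7, 3000)
        masks = segment_well([_field(image)])
        assert masks[0].n_objects == 4


class TestExcludeEdgeObjects:
    def test_border_crossing_object_removed(self):
        image = np.zeros((64, 64), dtype=np.uint16)
        draw_disk(image, 30, 30, 8, 100)    # interior
        draw_disk(image, 63, 30, 8, 100)    # crosses right border
        mask = segment_well([_field(image)])[0]
        assert mask.n_objects == 2
        cleaned = exclude_edge_objects(mask)
        assert cleaned.n_objects == 1
        assert not cleaned.labels[:, -1].any()

    def test_grid_keeps_interior_ring(self):
        image = np.zeros((59, 59), dtype=np.uint16)
        for i in range(5):
            for j in range(5):
                draw_disk(image, 5 + 12 * i, 5 + 12 * j, 5, 100)
        mask = segment_well([_field(image)])[0]
        assert mask.n_objects == 25
        assert exclude_edge_objects(mask).n_objects == 9

    def test_idempotent_and_area_never_grows(self):
        image = np.zeros((64, 64), dtype=np.uint16)
        draw_disk(image, 30, 30, 8, 100)
        draw_disk(image, 0, 50, 6, 100)
        mask = segment_well([_field(image)])[0]
        once = exclude_edge_objects(mask)
        twice = exclude_edge_objects(once)
        np.testing.assert_array_equal(once.labels, twice.labels)
        assert (once.labels > 0).sum() <= (mask.labels > 0).sum()

    def test_all_interior_is_identity(self):
        image = np.zeros((64, 64), dtype=np.uint16)
        draw_disk(image, 30, 30, 8, 100)
        mask = segment_well([_field(image)])[0]
        np.testing.assert_array_equal(exclude_edge_objects(mask).labels, mask.labels)

    def test_relabeling_is_contiguous(self):
        image = np.zeros((64, 64), dtype=np.uint16)
        draw_disk(image, 5, 0, 4, 100)      # touches top: removed
        draw_disk(image, 30, 30, 6, 100)
        draw_disk(image, 50, 50, 6, 100)
        cleaned = exclude_edge_objects(segment_well([_field(image)])[0])
        labels = np.unique(cleaned.labels)
        np.testing.assert_array_equal(labels, [0, 1, 2])


class TestObjectAreas:
    def test_square_area_calibrated(self):
        image = np.zeros((32, 32), dtype=np.uint16)
        image[5:16, 5:16] = 100
        mask = segment_well([_field(image, calibration=2.6)])[0]
        areas = object_areas(mask, calibration=2.6)
        assert areas[1] == (121, pytest.approx(121 * 6.76))

    def test_unit_calibration_identity(self):
        image = np.zeros((32, 32), dtype=np.uint16)
        image[5:16, 5:16] = 100
        mask = segment_well([_field(image)])[0]
        px, um2 = object_areas(mask, calibration=1.0)[1]
        assert px == um2

    @pytest.mark.parametrize("r", [10, 15, 20])
    def test_disk_area_close_to_analytic(self, r):
        image = np.zeros((64, 64), dtype=np.uint16)
        draw_disk(image, 31.5, 31.5, r, 100)
        mask = segment_well([_field(image)])[0]
        px, _ = object_areas(mask, calibration=1.0)[1]
        assert px == pytest.approx(np.pi * r * r, rel=0.05)

    def test_areas_sum_to_foreground_pixels(self, rng):
        image = (rng.random((64, 64)) < 0.4).astype(np.uint16) * 100
        mask = segment_well([_field(image)])[0]
        areas = object_areas(mask, calibration=1.0)
        assert sum(a for a, _ in areas.values()) == (mask.labels > 0).sum()
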