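"""Threshold segmentation, labelling and quality control."""

import math

import numpy as np
import pytest
from shapely.geometry import Point
from skimage.draw import disk, ellipse

from underice.detection import (
    Frame,
    QCReport,
    centered_crop_offset,
    crop_frame,
    flag_clumps,
    label_regions,
    qc_frames,
    qc_regions,
    threshold_green,
)


def _frame(pixels, frame_id=0, depth=2.0, tilt=0.0, altimeter=1.0):
    return Frame(frame_id=frame_id, t=0.0, depth=depth, tilt=tilt,
                 altimeter=altimeter, x=0.0, y=0.0, pixels=pixels)


def _rgb(green: np.ndarray) -> np.ndarray:
    return np.dstack([green, green, green]).astype(np.uint8)


class TestCrop:
    def test_centered_window_offsets(self):
        # ((288-200)/2, (384-250)/2) = (44, 67) in (row, col)
        assert centered_crop_offset() == (44, 67)

    def test_centered_crop_shape_and_metadata(self):
        fr = _frame(np.zeros((288, 384, 3), np.uint8), frame_id=9)
        out = crop_frame(fr)
        assert out.pixels.shape == (200, 250, 3)
        assert out.frame_id == 9 and out.altimeter == fr.altimeter

    def test_full_frame_crop_is_identity(self):
        fr = _frame(np.arange(200 * 250 * 3, dtype=np.uint8).reshape(200, 250, 3) % 255)
        out = crop_frame(fr, width=250, height=200, offset=(0, 0))
        assert np.array_equal(out.pixels, fr.pixels)

    def test_out_of_bounds_window_rejected(self):
        fr = _frame(np.zeros((288, 384, 3), np.uint8))
        with pytest.raises(ValueError):
            crop_frame(fr, offset=(100, 200))


class TestThreshold:
    def test_inclusive_band_boundaries(self):
        green = np.array([[100, 101], [0, 255]], dtype=np.uint8)
        mask = threshold_green(_rgb(green))
        assert mask.tolist() == [[True, False], [True, False]]

    def test_all_white_frame_is_empty(self):
        assert not threshold_green(_rgb(np.full((20, 20), 255, np.uint8))).any()

    def test_rethresholding_is_idempotent(self):
        rng = np.random.default_rng(0)
        img = _rgb(rng.integers(0, 256, (50, 50)).astype(np.uint8))
        m1 = threshold_green(img)
        # re-express the classification as an image and threshold again
        binary = _rgb(np.where(m1, 0, 255).astype(np.uint8))
        assert np.array_equal(threshold_green(binary), m1)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            threshold_green(_rgb(np.zeros((4, 4), np.uint8)), lo=50, hi=10)


class TestLabelRegions:
    def test_separated_ellipses_are_two_regions(self):
        m = np.zeros((100, 100), bool)
        for c in (25, 75):
            rr, cc = ellipse(50, c, 8, 12)
            m[rr, cc] = True
        assert len(label_regions(m)) == 2

    def test_single_pixel_region_has_no_ellipse(self):
        m = np.zeros((10, 10), bool)
        m[4, 4] = True
        (r,) = label_regions(m)
        assert r.pixel_area == 1
        assert r.major_axis is None and r.minor_axis is None

    def test_region_count_invariant_to_geometric_relabeling(self):
        rng = np.random.default_rng(1)
        m = rng.random((80, 80)) > 0.9
        n = len(label_regions(m))
        assert len(label_regions(m[::-1, :])) == n
        assert len(label_regions(m.T)) == n

    def test_empty_mask_gives_empty_list(self):
        assert label_regions(np.zeros((10, 10), bool)) == []


class TestFrameQC:
    def _frames(self, specs):
        return [
            _frame(None, frame_id=i, depth=d, tilt=t) for i, (d, t) in enumerate(specs)
        ]

    def test_deep_frame_discarded(self):
        valid, rep = qc_frames(self._frames([(6.0, 0.0)]))
        assert valid == [] and rep.n_discarded_depth == 1

    def test_boundary_values_retained(self):
        valid, rep = qc_frames(self._frames([(5.0, 10.0)]))
        assert len(valid) == 1 and rep.n_valid == 1

    def test_tilt_violations_counted(self):
        specs = [(2.0, 12.0)] * 3 + [(2.0, 1.0)] * 7
        valid, rep = qc_frames(self._frames(specs))
        assert rep.n_valid == 7 and rep.n_discarded_tilt == 3

    def test_missing_nav_discarded_with_reason(self):
        fr = _frame(None, frame_id=0)
        fr.altimeter = float("nan")
        valid, rep = qc_frames([fr])
        assert valid == [] and rep.reasons[0] == "missing-nav"

    def test_inconsistent_report_rejected(self):
        with pytest.raises(ValueError):
            QCReport(n_input=5, n_discarded_depth=1, n_discarded_tilt=0,
                     n_discarded_manual=0, n_valid=5)


class TestRegionQC:
    def _mask_with_areas(self, areas):
        """Horizontal 1-px-high runs with the requested pixel areas."""
        m = np.zeros((40, 400), bool)
        col = 5
        for i, a in enumerate(areas):
            m[3 * i + 2, col : col + a] = True
        return m

    def test_ten_pixel_boundary(self):
        regions = label_regions(self._mask_with_areas([10, 11]))
        # 1-px-high runs have degenerate ellipses; use compact blobs instead
        m = np.zeros((60, 60), bool)
        rr, cc = disk((15, 15), 1.9)  # area ~ 9-12 px
        m[rr, cc] = True
        regions = label_regions(m)
        area = regions[0].pixel_area
        measurable, detect_only = qc_regions(regions, min_shape_pixels=10)
        if area > 10:
            assert measurable and not detect_only
        else:
            assert detect_only and not measurable

    def test_partition_sizes_match_hand_count(self):
        m = self._mask_with_areas([3, 8, 10, 11, 25, 40])
        regions = label_regions(m)
        measurable, detect_only = qc_regions(regions, min_shape_pixels=10)
        assert len(measurable) + len(detect_only) == 6
        # 1-px-high runs carry no ellipse so they are detect-only regardless
        assert all(r.pixel_area <= 10 or r.minor_axis is None for r in detect_only)

    def test_empty_input(self):
        assert qc_regions([]) == ([], [])


class TestClumpFlag:
    def test_single_convex_ellipse_unflagged(self):
        m = np.zeros((80, 80), bool)
        rr, cc = ellipse(40, 40, 10, 16)
        m[rr, cc] = True
        measurable, _ = qc_regions(label_regions(m))
        assert flag_clumps(measurable) == [False]
        assert measurable[0].solidity > 0.95

    def test_bent_dumbbell_flagged_with_solidity_oracle(self):
        # two overlapping circles offset diagonally: clearly non-convex
        m = np.zeros((120, 120), bool)
        for r0, c0 in ((50, 40), (62, 54)):
            rr, cc = disk((r0, c0), 10)
            m[rr, cc] = True
        regions = label_regions(m)
        assert len(regions) == 1
        measurable, _ = qc_regions(regions)
        # continuum solidity of the same union, via an independent geometry lib
        union = Point(40, 50).buffer(10, quad_segs=64).union(
            Point(54, 62).buffer(10, quad_segs=64)
        )
        oracle = union.area / union.convex_hull.area
        assert measurable[0].solidity == pytest.approx(oracle, abs=0.05)
        assert oracle < 0.92  # the fixture really is below the cut
        assert flag_clumps(measurable, solidity_min=0.90) == [True]

    def test_all_flagged_leaves_abundance_unchanged(self):
        m = np.zeros((120, 240), bool)
        for c0 in (40, 120, 200):
            for dc in (0, 14):
                rr, cc = disk((60, c0 + dc), 9)
                m[rr, cc] = True
        regions = label_regions(m)
        measurable, _ = qc_regions(regions)
        flags = flag_clumps(measurable, solidity_min=0.98)
        assert all(flags)  # every region flagged...
        assert len(regions) == 3  # ...but they still count as detections
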