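"""Proportional geometric partition: band arithmetic, box construction,
mirror/translation equivariance, and the arch index."""

import numpy as np
import pytest

from plantarseg.contours import assign_regions, filter_by_area, trace_contours
from plantarseg.partition import (
    arch_index,
    band_lengths,
    build_partition,
    collect_foot_points,
    foot_length,
)
from plantarseg.types import (
    BinaryMask,
    IncompleteFootError,
    MissingFootError,
    ValidationError,
)


def rect_points(x0, x1, y0, y1):
    """All lattice points with x in [x0, x1], y in [y0, y1] (inclusive)."""
    xx, yy = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    return np.column_stack([xx.ravel(), yy.ravel()])


class TestFootLength:
    def test_full_span(self):
        pts = np.array([[5, 0], [9, 99], [7, 50]])
        assert foot_length(pts) == (0, 99, 100)

    def test_single_point(self):
        assert foot_length(np.array([[3, 7]])) == (7, 7, 1)

    def test_offset_span(self):
        pts = np.array([[0, 120], [0, 419]])
        assert foot_length(pts)[2] == 300

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            foot_length(np.empty((0, 2)))


class TestBandLengths:
    @pytest.mark.parametrize("length,expected", [(100, (30, 30, 40)), (10, (3, 3, 4))])
    def test_worked_examples(self, length, expected):
        assert band_lengths(length) == expected

    def test_conservation_exhaustive(self):
        for length in range(4, 2001):
            fore, arch, heel = band_lengths(length)
            assert fore + arch + heel == length
            assert fore >= 1 and arch >= 1 and heel >= 1

    @pytest.mark.parametrize("length", [0, 1, 2, 3])
    def test_degenerate_lengths_rejected(self, length):
        # length 3 floors the 30% bands to zero and must be refused
        with pytest.raises(ValidationError):
            band_lengths(length)


class TestBuildPartition:
    def test_forefoot_midpoint_split_left(self):
        # foot: uniform rectangle x in [0, 10], y in [0, 99]
        pts = rect_points(0, 10, 0, 99)
        part = build_partition(pts, "left", img_width=350)
        outer = part.boxes["outerForefoot"]
        inner = part.boxes["innerForefoot"]
        assert outer.x == 0 and outer.x2 == 5  # [0, 5)
        assert inner.x == 5 and inner.x2 == 11  # [5, 10] inclusive
        assert outer.y == inner.y == 0 and outer.h == inner.h == 30

    def test_band_boxes_of_length_100_foot(self):
        pts = rect_points(0, 10, 0, 99)
        part = build_partition(pts, "left", img_width=350)
        assert part.bands == (30, 30, 40)
        arch = part.boxes["midfoot"]
        heel = part.boxes["heel"]
        assert (arch.y, arch.y2) == (30, 60)
        assert (heel.y, heel.y2) == (60, 100)

    def test_y_intervals_tile_foot_exactly(self, small_foot):
        ys, xs = np.nonzero(small_foot.sole_mask)
        part = build_partition(np.column_stack([xs, ys]), "left", img_width=360)
        fore = part.boxes["outerForefoot"]
        arch = part.boxes["midfoot"]
        heel = part.boxes["heel"]
        assert fore.y == part.y_min
        assert fore.y2 == arch.y
        assert arch.y2 == heel.y
        assert heel.y2 == part.y_max + 1

    def test_right_foot_mirror_equivariance(self):
        # even forefoot x-span: the floor in the midpoint split is then
        # symmetric and the mirror is exact
        width = 350
        pts = rect_points(40, 90, 10, 159)
        left = build_partition(pts, "left", img_width=width)
        mirrored = pts.copy()
        mirrored[:, 0] = width - 1 - mirrored[:, 0]
        right = build_partition(mirrored, "right", img_width=width)
        for lbl in ("outerForefoot", "innerForefoot", "midfoot", "heel"):
            lb, rb = left.boxes[lbl], right.boxes[lbl]
            assert (lb.y, lb.h) == (rb.y, rb.h)
            # x-interval mirrors: [x, x2) -> [width - x2, width - x)
            assert rb.x == width - lb.x2 and rb.x2 == width - lb.x

    def test_translation_equivariance(self):
        pts = rect_points(5, 40, 8, 107)
        base = build_partition(pts, "left", img_width=1000)
        shifted = build_partition(pts + np.array([17, 23]), "left", img_width=1000)
        for lbl, b in base.boxes.items():
            s = shifted.boxes[lbl]
            assert (s.x, s.y, s.w, s.h) == (b.x + 17, b.y + 23, b.w, b.h)

    def test_empty_band_raises_naming_band(self):
        # points only in the top 30% and bottom 40%: the midfoot band is empty
        pts = np.vstack([rect_points(0, 10, 0, 29), rect_points(0, 10, 60, 99)])
        with pytest.raises(IncompleteFootError, match="midfoot"):
            build_partition(pts, "left", img_width=350)


class TestCollectFootPoints:
    def _mask_with_toes(self):
        fg = np.zeros((120, 100), bool)
        fg[30:110, 20:70] = True  # sole: area ~4000
        fg[10:16, 25:31] = True  # toe blob
        fg[10:15, 40:45] = True  # toe blob
        return BinaryMask(np.where(fg, np.uint8(255), np.uint8(0)))

    def test_area_filter_excludes_toes(self):
        cs = trace_contours(self._mask_with_toes())
        kept = filter_by_area(cs, 1000)
        regions = assign_regions(kept, img_width=200)
        pts = collect_foot_points(kept, regions, "left")
        assert pts[:, 1].min() == 30  # toe points (y < 16) are gone

    def test_missing_side_raises(self):
        cs = trace_contours(self._mask_with_toes())
        kept = filter_by_area(cs, 1000)
        regions = assign_regions(kept, img_width=200)
        with pytest.raises(MissingFootError, match="right"):
            collect_foot_points(kept, regions, "right")

    def test_two_contours_union(self):
        fg = np.zeros((200, 100), bool)
        fg[10:60, 20:70] = True  # forefoot pad
        fg[120:190, 25:65] = True  # heel pad (disconnected, high arch)
        mask = BinaryMask(np.where(fg, np.uint8(255), np.uint8(0)))
        cs = trace_contours(mask)
        kept = filter_by_area(cs, 1000)
        regions = assign_regions(kept, img_width=200)
        pts = collect_foot_points(kept, regions, "left")
        assert pts[:, 1].min() == 10 and pts[:, 1].max() == 189


class TestArchIndex:
    def test_uniform_rectangle_is_one_third_flat(self):
        pts = rect_points(0, 20, 0, 98)
        res = arch_index(pts)
        assert res.ai == pytest.approx(1 / 3, abs=2 / 99)
        assert res.category == "flat"

    def test_high_arch_category(self):
        # narrow waist: middle third carries ~15% of the area
        top = rect_points(0, 29, 0, 32)
        mid = rect_points(0, 9, 33, 65)
        bot = rect_points(0, 29, 66, 98)
        res = arch_index(np.vstack([top, mid, bot]))
        assert res.ai < 0.21
        assert res.category == "high_arch"

    def test_normal_category(self):
        # waist tuned so the middle third holds ~23% of the area
        top = rect_points(0, 29, 0, 32)
        mid = rect_points(0, 16, 33, 65)
        bot = rect_points(0, 29, 66, 98)
        res = arch_index(np.vstack([top, mid, bot]))
        assert 0.21 < res.ai < 0.26
        assert res.category == "normal"

    def test_category_consistency_on_synthetic_types(self):
        from plantarseg.synthdata import SynthSpec, generate

        ais = {}
        for ft in ("low_arch", "high_arch"):
            s = generate(SynthSpec(foot_type=ft, image_size=(360, 360), foot_length=210, seed=3))
            ys, xs = np.nonzero(s.sole_mask)
            ais[ft] = arch_index(np.column_stack([xs, ys])).ai
        assert ais["high_arch"] < ais["low_arch"]

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            arch_index(np.empty((0, 2)))
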