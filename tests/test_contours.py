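"""Border following, shoelace areas, area filtering and side assignment."""

import numpy as np
import pytest
from scipy import ndimage

from plantarseg.contours import (
    assign_regions,
    filter_by_area,
    shoelace_area,
    trace_contours,
)
from plantarseg.types import BinaryMask, Contour, ContourSet
from tests.conftest import make_blob_mask


def boundary_pixels(fg):
    """Oracle: foreground pixels 4-adjacent to the *outer* background
    (holes filled first, since only outer borders are traced)."""
    filled = ndimage.binary_fill_holes(fg)
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    eroded = ndimage.binary_erosion(filled, structure=cross, border_value=0)
    return fg & ~eroded


def as_mask(fg):
    return BinaryMask(np.where(fg, np.uint8(255), np.uint8(0)))


class TestTraceContours:
    def test_empty_mask(self):
        cs = trace_contours(as_mask(np.zeros((8, 8), bool)))
        assert len(cs) == 0

    def test_filled_square_boundary_points(self):
        fg = np.zeros((16, 16), bool)
        fg[3:13, 2:12] = True  # 10x10 square
        cs = trace_contours(as_mask(fg))
        assert len(cs) == 1
        pts = cs.contours[0].points
        # exactly the 36 boundary lattice pixels, each visited once
        expected = {(x, y) for y in range(3, 13) for x in range(2, 12)
                    if y in (3, 12) or x in (2, 11)}
        assert len(pts) == 36
        assert {tuple(p) for p in pts} == expected
        # consecutive points (wrapping) are 8-adjacent
        diffs = np.abs(np.diff(np.vstack([pts, pts[:1]]), axis=0))
        assert diffs.max() == 1

    def test_two_disjoint_blobs(self, rng):
        fg = np.zeros((40, 40), bool)
        fg[5:12, 5:12] = True
        fg[25:35, 20:33] = True
        cs = trace_contours(as_mask(fg))
        assert len(cs) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_boundary_enumeration_oracle(self, seed):
        rng = np.random.default_rng(5000 + seed)
        fg = make_blob_mask(rng) == 255
        cs = trace_contours(as_mask(fg))
        labels, n = ndimage.label(fg, structure=np.ones((3, 3), bool))
        assert len(cs) == n
        traced = set()
        for c in cs.contours:
            traced |= {tuple(p) for p in c.points}
        expect = {(x, y) for y, x in zip(*np.nonzero(boundary_pixels(fg)))}
        assert traced == expect

    def test_translation_equivariance(self, rng):
        fg = make_blob_mask(rng) == 255
        cs = trace_contours(as_mask(fg))
        padded = np.zeros((fg.shape[0] + 2, fg.shape[1] + 2), bool)
        padded[1:-1, 1:-1] = fg
        cs_pad = trace_contours(as_mask(padded))
        assert len(cs) == len(cs_pad)
        for a, b in zip(cs.contours, cs_pad.contours):
            assert np.array_equal(a.points + 1, b.points)

    def test_bounding_rect_contains_all_points(self, rng):
        fg = make_blob_mask(rng) == 255
        for c in trace_contours(as_mask(fg)).contours:
            box = c.bounding_rect()
            assert all(box.contains_point(x, y) for x, y in c.points)


class TestShoelace:
    def test_unit_square(self):
        c = Contour([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert shoelace_area(c) == 1.0

    def test_right_triangle(self):
        c = Contour([(0, 0), (4, 0), (0, 3)])
        assert shoelace_area(c) == 6.0

    def test_degenerate_returns_zero(self):
        assert shoelace_area(Contour([(0, 0), (5, 5)])) == 0.0

    def test_orientation_invariance(self, rng):
        pts = [(0, 0), (7, 1), (9, 6), (4, 9), (1, 5)]
        c = Contour(pts)
        r = Contour(pts[::-1])
        assert shoelace_area(c) == shoelace_area(r)

    def test_matches_shapely_exactly(self, rng):
        shapely = pytest.importorskip("shapely.geometry")
        for _ in range(20):
            pts = _random_star_polygon(rng)
            ours = shoelace_area(Contour(pts))
            theirs = shapely.Polygon(pts).area
            assert ours == pytest.approx(theirs, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_rasterization_oracle(self, seed):
        """Pixel-count oracle: |shoelace - filled pixel count| bounded by
        ~half the perimeter (lattice polygons through pixel centres)."""
        rng = np.random.default_rng(6000 + seed)
        pts = _random_star_polygon(rng)
        area = shoelace_area(Contour(pts))
        filled = _rasterize_polygon(pts, 64)
        perimeter = _perimeter(pts)
        assert abs(area - filled) <= perimeter / 2 + 1


def _random_star_polygon(rng, n=None, cx=32, cy=32, r_lo=8, r_hi=25):
    """Simple (non-self-intersecting) lattice polygon by angular sweep.

    Angles are kept >= 0.3 rad apart and radii >= 8 so that rounding the
    vertices to the lattice cannot reorder them around the centre (which
    would create a self-intersection)."""
    n = n or int(rng.integers(5, 12))
    while True:
        angles = np.sort(rng.uniform(0, 2 * np.pi, n))
        gaps = np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]]))
        if gaps.min() >= 0.3:
            break
    radii = rng.uniform(r_lo, r_hi, n)
    pts = [(int(round(cx + r * np.cos(a))), int(round(cy + r * np.sin(a))))
           for a, r in zip(angles, radii)]
    out = [p for i, p in enumerate(pts) if p != pts[i - 1]]
    return out if len(out) >= 3 else [(0, 0), (4, 0), (0, 3)]


def _rasterize_polygon(pts, size):
    from matplotlib.path import Path as MplPath

    yy, xx = np.mgrid[0:size, 0:size]
    grid = np.column_stack([xx.ravel(), yy.ravel()])
    inside = MplPath(pts).contains_points(grid, radius=0.0)
    return int(inside.sum())


def _perimeter(pts):
    arr = np.asarray(pts, float)
    d = np.diff(np.vstack([arr, arr[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


class TestFilterAndAssign:
    def _cs_with_areas(self, areas):
        tri = [(0, 0), (4, 0), (0, 3)]
        return ContourSet([Contour(tri) for _ in areas], list(areas))

    def test_strict_min_area_filter(self):
        cs = self._cs_with_areas([5999, 6000, 6001, 12000])
        kept = filter_by_area(cs, 6000)
        assert kept.areas == [6001, 12000]

    def test_filter_empty_and_identity(self):
        assert len(filter_by_area(self._cs_with_areas([]), 6000)) == 0
        cs = self._cs_with_areas([10, 20])
        assert filter_by_area(cs, 0).areas == [10, 20]

    def test_filter_idempotent(self):
        cs = self._cs_with_areas([100, 7000, 5000, 9000])
        once = filter_by_area(cs, 6000)
        twice = filter_by_area(once, 6000)
        assert once.areas == twice.areas

    def test_side_rule(self):
        left_c = Contour([(10, 0), (20, 0), (20, 10), (10, 10)])
        mid_c = Contour([(350, 0), (360, 0), (360, 10), (350, 10)])
        cs = ContourSet([left_c, mid_c], [100.0, 100.0])
        regions = assign_regions(cs, img_width=700)
        assert regions[0].side == "left"  # x=10 < 350
        assert regions[1].side == "right"  # x=350, not < 350

    def test_flanking_contours_split_sides(self):
        a = Contour([(100, 50), (150, 50), (150, 90), (100, 90)])
        b = Contour([(500, 50), (550, 50), (550, 90), (500, 90)])
        cs = ContourSet([a, b], [2000.0, 2000.0])
        sides = {r.side for r in assign_regions(cs, img_width=700)}
        assert sides == {"left", "right"}
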