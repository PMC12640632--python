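"""Closed-contour extraction and footprint box assignment.

Outer borders of 8-connected foreground components are traced with a
border-following (Moore neighbourhood) walk, giving an ordered closed
point sequence per component.  Contours are scored with the shoelace
formula, small ones (toes, sensor specks) are filtered by a strict
minimum-area rule, and survivors are boxed and assigned to the left or
right foot by the image midline.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .types import BinaryMask, Contour, ContourSet, FootRegion, Rect

__all__ = ["trace_contours", "shoelace_area", "filter_by_area", "assign_regions"]

log = logging.getLogger(__name__)

#: Default minimum contour area (px^2); toes and noise blobs fall below it.
DEFAULT_MIN_AREA = 6000.0

_STRUCT8 = np.ones((3, 3), dtype=bool)

# 8-neighbourhood in clockwise order (image coordinates, y down), as (dx, dy):
# E, SE, S, SW, W, NW, N, NE.
_NEIGHBORS = ((1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1))


def _trace_component(fg: np.ndarray, start: tuple[int, int]) -> np.ndarray:
    """Border-following trace of one 8-connected component's outer border.

    ``start`` is the component's first foreground pixel in raster order
    (its west neighbour is background), given as (y, x).  From the start
    pixel the first neighbour is sought clockwise beginning at west; the
    border is then followed by counterclockwise neighbourhood scans, and
    the walk terminates when it is back at the start pixel about to repeat
    its first move.  Returns the ordered closed boundary as an (n, 2)
    array of (x, y) points; spur pixels may legitimately appear twice.
    """
    h, w = fg.shape
    sy, sx = start

    def is_fg(y: int, x: int) -> bool:
        return 0 <= y < h and 0 <= x < w and fg[y, x]

    # find the first nonzero neighbour, scanning clockwise from west
    p1_dir = None
    for step in range(8):
        d = (4 + step) % 8
        dx, dy = _NEIGHBORS[d]
        if is_fg(sy + dy, sx + dx):
            p1_dir = d
            break
    if p1_dir is None:  # isolated pixel
        return np.asarray([(sx, sy)], dtype=np.int64)

    dx, dy = _NEIGHBORS[p1_dir]
    p1 = (sy + dy, sx + dx)
    points = [(sx, sy)]
    p3 = (sy, sx)
    back = p1_dir  # direction from p3 towards the previously examined pixel
    while True:
        # counterclockwise scan around p3 starting just past the backtrack
        y, x = p3
        for step in range(1, 9):
            nd = (back - step) % 8
            dx, dy = _NEIGHBORS[nd]
            p4 = (y + dy, x + dx)
            if is_fg(*p4):
                break
        if p4 == (sy, sx) and p3 == p1:
            break  # about to re-trace the first move: border closed
        p3 = p4
        back = (nd + 4) % 8
        points.append((p3[1], p3[0]))
        if len(points) > 4 * fg.size:  # pragma: no cover - safety net
            raise RuntimeError("border following failed to terminate")
    return np.asarray(points, dtype=np.int64)


def trace_contours(mask: BinaryMask) -> ContourSet:
    """Outer border contours of all 8-connected foreground components.

    One contour per component, ordered by the raster position of the
    component's topmost-leftmost pixel; holes (inner borders) are ignored.
    An empty mask yields an empty :class:`ContourSet`.
    """
    fg = mask.foreground
    labels, n = ndimage.label(fg, structure=_STRUCT8)
    contours: list[Contour] = []
    areas: list[float] = []
    if n == 0:
        return ContourSet(contours, areas)
    # first pixel of each component in raster order
    flat = labels.ravel()
    order = np.argsort(flat, kind="stable")
    first_idx = np.searchsorted(flat[order], np.arange(1, n + 1))
    starts = order[first_idx]
    ys, xs = np.unravel_index(starts, fg.shape)
    comp_order = np.argsort(ys * fg.shape[1] + xs)
    for k in comp_order:
        comp = labels == (k + 1)
        pts = _trace_component(comp, (int(ys[k]), int(xs[k])))
        c = Contour(pts)
        contours.append(c)
        areas.append(shoelace_area(c))
    return ContourSet(contours, areas)


def shoelace_area(c: Contour) -> float:
    """Absolute shoelace (surveyor's) area of a closed lattice polygon:
    ``1/2 |sum_j (x_j y_{j+1} - x_{j+1} y_j)|``, orientation independent.
    Contours with fewer than 3 points enclose no area and return 0."""
    pts = c.points
    if len(pts) < 3:
        return 0.0
    x = pts[:, 0].astype(np.float64)
    y = pts[:, 1].astype(np.float64)
    xn = np.roll(x, -1)
    yn = np.roll(y, -1)
    return float(abs(np.sum(x * yn - xn * y)) / 2.0)


def filter_by_area(cs: ContourSet, min_area: float = DEFAULT_MIN_AREA) -> ContourSet:
    """Keep contours whose area is strictly greater than ``min_area``;
    order is preserved.  The default of 6000 px^2 removes toe blobs and
    sensor noise while keeping sole regions."""
    kept = [(c, a) for c, a in zip(cs.contours, cs.areas) if a > min_area]
    return ContourSet([c for c, _ in kept], [a for _, a in kept])


def assign_regions(cs: ContourSet, img_width: int) -> list[FootRegion]:
    """Bounding box per contour, assigned to a side by the image midline:
    left iff ``box.x < img_width / 2`` (strict), else right.

    A box straddling the midline is assigned left by this rule; that case
    is logged because it usually indicates touching feet or a bad mask.
    """
    regions: list[FootRegion] = []
    half = img_width / 2
    for i, c in enumerate(cs.contours):
        box = c.bounding_rect()
        side = "left" if box.x < half else "right"
        if box.x < half <= box.x2 - 1:
            log.warning("contour %d straddles the midline (box %s); assigned left", i, box)
        regions.append(FootRegion(side=side, box=box, source_contours=(i,)))
    return regions


def foot_boxes(regions: list[FootRegion]) -> dict[str, Rect]:
    """Union box per side (smallest Rect covering all that side's boxes)."""
    out: dict[str, Rect] = {}
    for side in ("left", "right"):
        boxes = [r.box for r in regions if r.side == side]
        if not boxes:
            continue
        x0 = min(b.x for b in boxes)
        y0 = min(b.y for b in boxes)
        x1 = max(b.x2 for b in boxes)
        y1 = max(b.y2 for b in boxes)
        out[side] = Rect(x0, y0, x1 - x0, y1 - y0)
    return out
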