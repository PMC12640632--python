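"""Proportional geometric partition of a footprint into anatomical regions.

Given the toe-excluded contour points of one foot, the foot length along
the image y axis is split into forefoot / midfoot (arch) / heel bands in
the standard 30% / 30% / 40% proportions, the forefoot band is halved at
its x midpoint into outer (lateral) and inner (medial) parts, and each
band becomes an axis-aligned box spanning the x extent of the points that
fall inside it.  The same rule applied to a filled footprint mask also
yields the arch index used for flat / normal / high-arch grading.
"""

from __future__ import annotations

import numpy as np

from .types import (
    ArchIndexResult,
    ContourSet,
    FootPartition,
    FootRegion,
    IncompleteFootError,
    MissingFootError,
    Rect,
    ValidationError,
)

__all__ = [
    "collect_foot_points",
    "foot_length",
    "band_lengths",
    "build_partition",
    "arch_index",
]

#: Band proportions along foot length: forefoot, arch, heel.
BAND_PROPORTIONS = (0.3, 0.3, 0.4)

#: Arch-index category thresholds.
AI_HIGH_ARCH_MAX = 0.21
AI_FLAT_MIN = 0.26


def collect_foot_points(
    cs: ContourSet, regions: list[FootRegion], side: str
) -> np.ndarray:
    """Union of contour points of all filtered contours assigned to ``side``.

    Toe exclusion happens upstream: toe blobs fall below the contour area
    filter and never reach this stage.  Raises :class:`MissingFootError`
    when no contour lies on the requested side.
    """
    idx = [i for r in regions if r.side == side for i in r.source_contours]
    if not idx:
        raise MissingFootError(f"no filtered contour on the {side} side")
    pts = np.concatenate([cs.contours[i].points for i in idx], axis=0)
    return np.unique(pts, axis=0)


def foot_length(points: np.ndarray) -> tuple[int, int, int]:
    """Inclusive pixel length of the foot along y.

    Returns ``(y_min, y_max, length)`` with ``length = y_max - y_min + 1``.
    """
    pts = np.asarray(points)
    if pts.size == 0:
        raise ValidationError("empty point set")
    y = pts[:, 1]
    y_min, y_max = int(y.min()), int(y.max())
    return y_min, y_max, y_max - y_min + 1


def band_lengths(length: int) -> tuple[int, int, int]:
    """Split a foot length into (forefoot, arch, heel) band lengths.

    Forefoot and arch take ``floor(0.3 * length)`` each; the heel absorbs
    the remainder so the three bands always sum to ``length`` exactly.
    Lengths too short to give every band at least one pixel are rejected.
    """
    if length < 3:
        raise ValidationError(f"foot length {length} too short to partition")
    fore = int(length * BAND_PROPORTIONS[0])
    arch = int(length * BAND_PROPORTIONS[1])
    heel = length - fore - arch
    if fore == 0 or arch == 0 or heel == 0:
        raise ValidationError(f"degenerate foot: bands {(fore, arch, heel)} for length {length}")
    return fore, arch, heel


def _band_extent(pts: np.ndarray, y0: int, y1: int, name: str) -> tuple[int, int]:
    """Min/max x of points with y in [y0, y1); errors when the band is empty."""
    sel = pts[(pts[:, 1] >= y0) & (pts[:, 1] < y1)]
    if sel.size == 0:
        raise IncompleteFootError(f"no foot points in the {name} band (y in [{y0}, {y1}))")
    return int(sel[:, 0].min()), int(sel[:, 0].max())


def build_partition(points: np.ndarray, side: str, img_width: int) -> FootPartition:
    """Partition one foot's points into the four anatomical region boxes.

    The forefoot band is split vertically at
    ``minF_x + (maxF_x - minF_x) // 2``.  For a left foot the lower-x
    (lateral) half is the outer forefoot; for a right foot the assignment
    mirrors, so "outer" is always lateral and "inner" always medial.
    """
    pts = np.asarray(points, dtype=np.int64)
    y_min, y_max, length = foot_length(pts)
    fore, arch, heel = band_lengths(length)

    b_fore = (y_min, y_min + fore)
    b_arch = (y_min + fore, y_min + fore + arch)
    b_heel = (y_min + fore + arch, y_max + 1)
    minF_x, maxF_x = _band_extent(pts, *b_fore, "forefoot")
    minA_x, maxA_x = _band_extent(pts, *b_arch, "midfoot")
    minH_x, maxH_x = _band_extent(pts, *b_heel, "heel")

    # the left foot splits at minF_x + (maxF_x - minF_x) // 2 with the
    # lateral (lower-x) half as the outer forefoot; the right foot is the
    # exact mirror of that construction, so its lateral (higher-x) outer
    # half has the same width d // 2 and the split sits at maxF_x+1 - d//2
    outer_w = max((maxF_x - minF_x) // 2, 1)
    if side == "left":
        split = minF_x + outer_w
        outer = Rect(minF_x, b_fore[0], outer_w, fore)
        inner = Rect(split, b_fore[0], maxF_x + 1 - split, fore)
    elif side == "right":
        split = maxF_x + 1 - outer_w
        inner = Rect(minF_x, b_fore[0], split - minF_x, fore)
        outer = Rect(split, b_fore[0], outer_w, fore)
    else:
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")

    boxes = {
        "outerForefoot": outer,
        "innerForefoot": inner,
        "midfoot": Rect(minA_x, b_arch[0], maxA_x - minA_x + 1, arch),
        "heel": Rect(minH_x, b_heel[0], maxH_x - minH_x + 1, heel),
    }
    if img_width is not None:
        for lbl, b in boxes.items():
            if b.x < 0 or b.x2 > img_width:
                raise ValidationError(f"{lbl} box {b} exceeds image width {img_width}")
    return FootPartition(
        side=side,
        foot_length=length,
        bands=(fore, arch, heel),
        boxes=boxes,
        y_min=y_min,
        y_max=y_max,
        x_extents={
            "forefoot": (minF_x, maxF_x),
            "midfoot": (minA_x, maxA_x),
            "heel": (minH_x, maxH_x),
        },
    )


def arch_index(mask_points: np.ndarray) -> ArchIndexResult:
    """Arch index of a toe-excluded filled footprint.

    ``mask_points`` are the (x, y) coordinates of the foreground pixels of
    one foot (the filled sole, not just its contour).  The footprint is
    cut into equal y-thirds and the index is the middle third's share of
    the total area: AI <= 0.21 is a high arch, AI >= 0.26 a flat foot,
    anything in between normal.
    """
    pts = np.asarray(mask_points)
    if pts.size == 0:
        raise ValidationError("empty point set")
    y_min, y_max, length = foot_length(pts)
    t1 = y_min + round(length / 3)
    t2 = y_min + round(2 * length / 3)
    y = pts[:, 1]
    mid = int(np.count_nonzero((y >= t1) & (y < t2)))
    ai = mid / len(pts)
    if ai <= AI_HIGH_ARCH_MAX:
        category = "high_arch"
    elif ai < AI_FLAT_MIN:
        category = "normal"
    else:
        category = "flat"
    return ArchIndexResult(ai=ai, category=category)
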