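"""Core domain types shared across the plantarseg pipeline.

Coordinate convention (fixed repo-wide): origin at the top-left corner,
``x`` increases rightward (column index), ``y`` increases downward (row
index).  Rectangles use half-open pixel semantics ``[x, x+w) x [y, y+h)``
so that areas are exact integer pixel counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The four anatomical region labels produced by the geometric partition.
REGION_LABELS = ("outerForefoot", "innerForefoot", "midfoot", "heel")

#: Valid foot sides.
SIDES = ("left", "right")


class PlantarSegError(Exception):
    """Base class for all plantarseg errors."""


class FormatError(PlantarSegError):
    """Unsupported image format or bit depth."""


class SchemaError(PlantarSegError):
    """Malformed or unrecognised annotation content."""


class ValidationError(PlantarSegError):
    """Parameter or geometry outside its documented domain."""


class DegenerateInputError(PlantarSegError):
    """Input that is technically well formed but carries no usable signal
    (e.g. a constant image handed to Otsu thresholding)."""


class MissingFootError(PlantarSegError):
    """No contour survived filtering on the requested foot side."""


class IncompleteFootError(PlantarSegError):
    """A proportional band of the foot contains no foreground points."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned box with half-open semantics ``[x, x+w) x [y, y+h)``."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValidationError(f"Rect extents must be >= 1, got w={self.w} h={self.h}")

    @property
    def area(self) -> int:
        return self.w * self.h

    @property
    def x2(self) -> int:
        """Exclusive right edge."""
        return self.x + self.w

    @property
    def y2(self) -> int:
        """Exclusive bottom edge."""
        return self.y + self.h

    def intersection_area(self, other: "Rect") -> int:
        iw = min(self.x2, other.x2) - max(self.x, other.x)
        ih = min(self.y2, other.y2) - max(self.y, other.y)
        if iw <= 0 or ih <= 0:
            return 0
        return iw * ih

    def contains_point(self, x: int, y: int) -> bool:
        return self.x <= x < self.x2 and self.y <= y < self.y2

    def as_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "w": self.w, "h": self.h}


def _as_uint8_grid(pixels) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2D grid, got shape {arr.shape}")
    if arr.size == 0:
        raise ValidationError("empty pixel grid")
    if arr.dtype != np.uint8:
        if np.any((arr < 0) | (arr > 255)):
            raise ValidationError("intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


@dataclass
class PressureImage:
    """A 2D 8-bit plantar pressure map.

    Intensities are raw sensor counts in ``[0, 255]``; multiplying by
    ``pressure_scale`` converts to kPa (the reference scanner maps one
    count to one kPa, hence the default of 1.0).
    """

    pixels: np.ndarray
    pressure_scale: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = _as_uint8_grid(self.pixels)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BinaryMask:
    """Strictly binary grid with foreground 255 and background 0."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = _as_uint8_grid(self.pixels)
        bad = np.setdiff1d(np.unique(self.pixels), [0, 255])
        if bad.size:
            raise ValidationError(f"mask values must be 0 or 255, found {bad.tolist()}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def foreground(self) -> np.ndarray:
        return self.pixels == 255


@dataclass
class Contour:
    """Ordered closed boundary on the pixel lattice.

    ``points`` is an ``(n, 2)`` integer array of ``(x, y)`` pairs;
    consecutive points (and last-to-first) are 8-adjacent.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.int64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError(f"contour points must be (n, 2), got {pts.shape}")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    def bounding_rect(self) -> Rect:
        xs, ys = self.points[:, 0], self.points[:, 1]
        x0, y0 = int(xs.min()), int(ys.min())
        return Rect(x0, y0, int(xs.max()) - x0 + 1, int(ys.max()) - y0 + 1)


@dataclass
class ContourSet:
    contours: list[Contour] = field(default_factory=list)
    areas: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.contours) != len(self.areas):
            raise ValidationError("contours and areas must align")
        if any(a < 0 for a in self.areas):
            raise ValidationError("contour areas must be non-negative")

    def __len__(self) -> int:
        return len(self.contours)


@dataclass(frozen=True)
class FootRegion:
    """One filtered contour's bounding box, assigned to a foot side."""

    side: str
    box: Rect
    source_contours: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")


@dataclass(frozen=True)
class GroundTruthBox:
    foot_side: str
    region_label: str
    box: Rect

    def __post_init__(self) -> None:
        if self.foot_side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.foot_side!r}")
        if self.region_label not in REGION_LABELS:
            raise ValidationError(
                f"label must be one of {REGION_LABELS}, got {self.region_label!r}"
            )


@dataclass
class FootPartition:
    """The four anatomical boxes of one foot plus the geometry they came from."""

    side: str
    foot_length: int
    bands: tuple[int, int, int]  # (fore, arch, heel) lengths in px
    boxes: dict[str, Rect]  # region label -> Rect
    y_min: int
    y_max: int
    x_extents: dict[str, tuple[int, int]]  # band name -> (min_x, max_x)

    def as_ground_truth(self) -> list[GroundTruthBox]:
        return [GroundTruthBox(self.side, lbl, self.boxes[lbl]) for lbl in REGION_LABELS]


@dataclass(frozen=True)
class ArchIndexResult:
    """Arch index: midfoot share of the toe-excluded footprint area."""

    ai: float
    category: str  # high_arch | normal | flat
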