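"""Binary segmentation backends for plantar pressure images.

Three families are provided, mirroring the classical comparison for this
task: global/adaptive thresholding, quadtree region split-and-merge, and a
five-stage Canny edge detector implemented from first principles
(Gaussian smoothing, Sobel gradients, non-maximum suppression, double
thresholding, hysteresis).  All backends return a :class:`BinaryMask`
with the same shape as the input and strictly binary values.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import (
    BinaryMask,
    DegenerateInputError,
    PressureImage,
    ValidationError,
)

__all__ = [
    "ThresholdParams",
    "SplitMergeParams",
    "CannyParams",
    "threshold_simple",
    "threshold_otsu",
    "threshold_adaptive",
    "split_merge",
    "canny",
    "PRESETS",
]


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdParams:
    method: str = "simple"  # simple | otsu | adaptive
    thresh: int = 127
    max_val: int = 255
    adaptive_block: int = 31
    adaptive_C: float = 2.0

    def __post_init__(self) -> None:
        if self.method not in ("simple", "otsu", "adaptive"):
            raise ValidationError(f"unknown threshold method {self.method!r}")
        if not 0 <= self.thresh <= 255:
            raise ValidationError(f"thresh must be in [0, 255], got {self.thresh}")
        if not 0 <= self.max_val <= 255:
            raise ValidationError(f"max_val must be in [0, 255], got {self.max_val}")
        if self.adaptive_block < 3 or self.adaptive_block % 2 == 0:
            raise ValidationError(
                f"adaptive_block must be odd and >= 3, got {self.adaptive_block}"
            )


@dataclass(frozen=True)
class SplitMergeParams:
    min_region: int = 16  # smallest splittable block side, power of two
    homogeneity_tol: int = 16  # max-min intensity range of a homogeneous region
    min_thresh: int = 50
    max_thresh: int = 100

    def __post_init__(self) -> None:
        if self.min_region < 1 or (self.min_region & (self.min_region - 1)):
            raise ValidationError(
                f"min_region must be a power of two >= 1, got {self.min_region}"
            )
        if self.homogeneity_tol < 0:
            raise ValidationError("homogeneity_tol must be >= 0")
        if not self.min_thresh < self.max_thresh:
            raise ValidationError(
                f"need min_thresh < max_thresh, got ({self.min_thresh}, {self.max_thresh})"
            )


@dataclass(frozen=True)
class CannyParams:
    gaussian_sigma: float = 0.6
    gaussian_ksize: int = 5
    min_val: float = 100.0
    max_val: float = 200.0

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValidationError("gaussian_sigma must be > 0")
        if self.gaussian_ksize < 1 or self.gaussian_ksize % 2 == 0:
            raise ValidationError("gaussian_ksize must be odd and >= 1")
        if not self.min_val < self.max_val:
            raise ValidationError(
                f"need min_val < max_val, got ({self.min_val}, {self.max_val})"
            )


#: Named parameter presets for the three backends.  The Canny pairs span the
#: detail/robustness trade-off; the highest pair keeps only the outer foot
#: contour, which is what the hybrid geometric method consumes.
PRESETS = {
    "threshold": {"default": ThresholdParams(method="simple", thresh=127)},
    "splitmerge": {"default": SplitMergeParams(min_thresh=50, max_thresh=100)},
    "canny": {
        "fine": CannyParams(min_val=100, max_val=200),
        "medium": CannyParams(min_val=200, max_val=300),
        "outer": CannyParams(min_val=300, max_val=600),
    },
}


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------


def threshold_simple(img: PressureImage, params: ThresholdParams | None = None) -> BinaryMask:
    """Global binarisation: ``dst = max_val`` where ``src > thresh`` (strict),
    else 0."""
    params = params or ThresholdParams()
    if params.method != "simple":
        raise ValidationError(f"threshold_simple requires method='simple', got {params.method!r}")
    out = np.where(img.pixels > params.thresh, np.uint8(params.max_val), np.uint8(0))
    return BinaryMask(_binarize(out))


def otsu_threshold_value(pixels: np.ndarray) -> int:
    """Threshold maximising between-class variance over the 256-bin histogram.

    Returns the intensity ``t`` such that the classes ``<= t`` and ``> t``
    have maximal between-class variance; ties resolve to the smallest ``t``.
    """
    hist = np.bincount(pixels.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    p = hist / total
    omega = np.cumsum(p)  # P(class0) for t = 0..255
    mu = np.cumsum(p * np.arange(256))
    mu_t = mu[-1]
    valid = (omega > 0) & (omega < 1)
    if not np.any(valid):
        raise DegenerateInputError("Otsu thresholding needs >= 2 distinct intensities")
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~valid] = -1.0
    return int(np.argmax(sigma_b))


def threshold_otsu(img: PressureImage, max_val: int = 255) -> tuple[int, BinaryMask]:
    """Otsu's method; returns ``(threshold, mask)`` with the mask binarised
    by the same strict ``>`` rule as simple thresholding."""
    t = otsu_threshold_value(img.pixels)
    mask = np.where(img.pixels > t, np.uint8(max_val), np.uint8(0))
    return t, BinaryMask(_binarize(mask))


def threshold_adaptive(img: PressureImage, params: ThresholdParams) -> BinaryMask:
    """Mean-adaptive binarisation: per-pixel threshold is the local
    ``adaptive_block`` mean minus ``adaptive_C``; comparison is strict ``>``.
    Borders use reflect padding."""
    if params.method != "adaptive":
        raise ValidationError(
            f"threshold_adaptive requires method='adaptive', got {params.method!r}"
        )
    b = params.adaptive_block
    if b > min(img.height, img.width):
        raise ValidationError(
            f"adaptive_block {b} exceeds image extent {img.width}x{img.height}"
        )
    local_mean = ndimage.uniform_filter(img.pixels.astype(np.float64), size=b, mode="reflect")
    out = np.where(
        img.pixels.astype(np.float64) > local_mean - params.adaptive_C,
        np.uint8(params.max_val),
        np.uint8(0),
    )
    return BinaryMask(_binarize(out))


def _binarize(arr: np.ndarray) -> np.ndarray:
    return np.where(arr > 0, np.uint8(255), np.uint8(0))


# ---------------------------------------------------------------------------
# region split and merge
# ---------------------------------------------------------------------------


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def _quadtree_labels(padded: np.ndarray, min_region: int, tol: int) -> np.ndarray:
    """Split the (square, power-of-two) image into homogeneous quadtree leaves.

    A block is homogeneous when its intensity range (max - min) is <= tol.
    Returns an int label map; labels are assigned coarse-to-fine in raster
    order, which fixes the region creation order deterministically.
    """
    size = padded.shape[0]
    labels = np.zeros(padded.shape, dtype=np.int64)
    next_label = 1
    # FIFO over blocks: (y, x, side)
    queue: deque[tuple[int, int, int]] = deque([(0, 0, size)])
    while queue:
        y, x, side = queue.popleft()
        block = padded[y : y + side, x : x + side]
        rng = int(block.max()) - int(block.min())
        if rng <= tol or side <= min_region or side == 1:
            labels[y : y + side, x : x + side] = next_label
            next_label += 1
        else:
            half = side // 2
            queue.append((y, x, half))
            queue.append((y, x + half, half))
            queue.append((y + half, x, half))
            queue.append((y + half, x + half, half))
    return labels


def _adjacent_label_pairs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Unique 4-adjacent label pairs (i < j), in sorted order."""
    pairs = set()
    a, b = labels[:, :-1], labels[:, 1:]
    diff = a != b
    pairs.update(zip(np.minimum(a[diff], b[diff]).tolist(), np.maximum(a[diff], b[diff]).tolist()))
    a, b = labels[:-1, :], labels[1:, :]
    diff = a != b
    pairs.update(zip(np.minimum(a[diff], b[diff]).tolist(), np.maximum(a[diff], b[diff]).tolist()))
    return sorted(pairs)


def split_merge(img: PressureImage, params: SplitMergeParams | None = None) -> BinaryMask:
    """Quadtree split followed by merging of adjacent jointly-homogeneous
    regions; the output marks pixels of regions whose mean intensity lies
    strictly inside ``(min_thresh, max_thresh)``.

    The image is zero-padded to the next power-of-two square so every split
    yields four equal sub-regions, then cropped back.  Merging runs to a
    fixpoint: no two adjacent surviving regions jointly satisfy the
    homogeneity criterion (combined intensity range <= homogeneity_tol).
    Candidate pairs are processed FIFO in region-creation order, so the
    result is deterministic.
    """
    params = params or SplitMergeParams()
    h, w = img.pixels.shape
    final_labels, padded = _split_merge_labels(img, params)
    n = int(final_labels.max())
    flat = final_labels.ravel()
    sums = np.bincount(flat, weights=padded.ravel().astype(np.float64), minlength=n + 1)
    counts = np.bincount(flat, minlength=n + 1)
    mean_of = np.zeros(n + 1)
    nz = counts > 0
    mean_of[nz] = sums[nz] / counts[nz]
    region_mean = mean_of[final_labels]
    out = np.where(
        (region_mean > params.min_thresh) & (region_mean < params.max_thresh),
        np.uint8(255),
        np.uint8(0),
    )
    return BinaryMask(out[:h, :w])


def split_merge_regions(img: PressureImage, params: SplitMergeParams | None = None) -> np.ndarray:
    """Final merged region label map (cropped to the image), for inspection
    and invariant testing.  Labels are positive ints; equal label = one region."""
    params = params or SplitMergeParams()
    h, w = img.pixels.shape
    final_labels, _ = _split_merge_labels(img, params)
    return final_labels[:h, :w]


def _split_merge_labels(
    img: PressureImage, params: SplitMergeParams
) -> tuple[np.ndarray, np.ndarray]:
    h, w = img.pixels.shape
    size = _next_pow2(max(h, w))
    padded = np.zeros((size, size), dtype=np.uint8)
    padded[:h, :w] = img.pixels
    labels = _quadtree_labels(padded, params.min_region, params.homogeneity_tol)
    return _merge_labels(padded, labels, params), padded


def _merge_labels(padded: np.ndarray, labels: np.ndarray, params: SplitMergeParams) -> np.ndarray:
    n = int(labels.max())
    mins = ndimage.minimum(padded, labels=labels, index=np.arange(1, n + 1))
    maxs = ndimage.maximum(padded, labels=labels, index=np.arange(1, n + 1))
    lo = np.empty(n + 1)
    hi = np.empty(n + 1)
    lo[1:] = mins
    hi[1:] = maxs
    parent = np.arange(n + 1)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    neighbors: list[set[int]] = [set() for _ in range(n + 1)]
    initial_pairs = _adjacent_label_pairs(labels)
    for i, j in initial_pairs:
        neighbors[i].add(j)
        neighbors[j].add(i)
    queue: deque[tuple[int, int]] = deque(initial_pairs)
    while queue:
        i, j = queue.popleft()
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        if rj not in neighbors[ri] and ri not in neighbors[rj]:
            continue
        if max(hi[ri], hi[rj]) - min(lo[ri], lo[rj]) > params.homogeneity_tol:
            continue
        if rj < ri:
            ri, rj = rj, ri
        parent[rj] = ri
        lo[ri] = min(lo[ri], lo[rj])
        hi[ri] = max(hi[ri], hi[rj])
        merged_nb = (neighbors[ri] | neighbors[rj]) - {ri, rj}
        canon = sorted({find(k) for k in merged_nb} - {ri})
        neighbors[ri] = set(canon)
        neighbors[rj] = set()
        for k in canon:
            neighbors[k].discard(rj)
            neighbors[k].add(ri)
            queue.append((min(ri, k), max(ri, k)))
    roots = np.array([find(i) for i in range(n + 1)])
    return roots[labels]


# ---------------------------------------------------------------------------
# Canny
# ---------------------------------------------------------------------------


def gaussian_kernel1d(sigma: float, ksize: int) -> np.ndarray:
    """Normalised 1-D Gaussian taps of odd length ``ksize``."""
    r = ksize // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_SOBEL_Y = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=np.float64)


def canny_gradients(img: PressureImage, params: CannyParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stages 1-2: Gaussian smoothing then 3x3 Sobel gradients.

    Returns ``(gx, gy, magnitude)`` with unnormalised L2 magnitude (it may
    exceed 255, which is what makes high double-threshold pairs such as
    (300, 600) meaningful on 8-bit input).  Borders reflect.
    """
    k = gaussian_kernel1d(params.gaussian_sigma, params.gaussian_ksize)
    smooth = ndimage.correlate1d(img.pixels.astype(np.float64), k, axis=0, mode="reflect")
    smooth = ndimage.correlate1d(smooth, k, axis=1, mode="reflect")
    gx = ndimage.correlate(smooth, _SOBEL_X, mode="reflect")
    gy = ndimage.correlate(smooth, _SOBEL_Y, mode="reflect")
    mag = np.hypot(gx, gy)
    return gx, gy, mag


def _nms(mag: np.ndarray, gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Stage 3: non-maximum suppression with the gradient direction quantised
    to 4 bins (0, 45, 90, 135 degrees); neighbours are taken on the lattice
    (nearest-neighbour, no interpolation).  A pixel survives when its
    magnitude is >= both neighbours along its direction."""
    angle = np.rad2deg(np.arctan2(gy, gx)) % 180.0
    # bin edges at 22.5 deg steps
    bins = np.zeros(angle.shape, dtype=np.int8)
    bins[(angle >= 22.5) & (angle < 67.5)] = 1  # 45 deg
    bins[(angle >= 67.5) & (angle < 112.5)] = 2  # 90 deg
    bins[(angle >= 112.5) & (angle < 157.5)] = 3  # 135 deg

    padded = np.pad(mag, 1, mode="constant")
    center = padded[1:-1, 1:-1]
    east = padded[1:-1, 2:]
    west = padded[1:-1, :-2]
    south = padded[2:, 1:-1]
    north = padded[:-2, 1:-1]
    se = padded[2:, 2:]
    nw = padded[:-2, :-2]
    ne = padded[:-2, 2:]
    sw = padded[2:, :-2]

    keep = np.zeros(mag.shape, dtype=bool)
    # 0 deg: gradient along x -> compare east/west
    m = bins == 0
    keep[m] = (center[m] >= east[m]) & (center[m] >= west[m])
    # 45 deg: gradient along +x+y diagonal -> compare se/nw
    m = bins == 1
    keep[m] = (center[m] >= se[m]) & (center[m] >= nw[m])
    # 90 deg: gradient along y -> compare north/south
    m = bins == 2
    keep[m] = (center[m] >= north[m]) & (center[m] >= south[m])
    # 135 deg: gradient along -x+y diagonal -> compare sw/ne
    m = bins == 3
    keep[m] = (center[m] >= sw[m]) & (center[m] >= ne[m])
    keep &= mag > 0
    return keep


_STRUCT8 = np.ones((3, 3), dtype=bool)


def canny(img: PressureImage, params: CannyParams | None = None) -> BinaryMask:
    """Five-stage Canny edge detector.

    1. Gaussian smoothing; 2. Sobel gradients (L2 magnitude); 3. non-maximum
    suppression along the quantised gradient direction; 4. double
    thresholding into strong (``>= max_val``) / weak (``>= min_val``) /
    non-edge; 5. hysteresis keeping weak pixels 8-connected to a strong one.
    """
    params = params or CannyParams()
    gx, gy, mag = canny_gradients(img, params)
    thin = _nms(mag, gx, gy)
    strong = thin & (mag >= params.max_val)
    weak = thin & (mag >= params.min_val)
    if not strong.any():
        return BinaryMask(np.zeros(img.pixels.shape, dtype=np.uint8))
    labels, _ = ndimage.label(weak, structure=_STRUCT8)
    keep_ids = np.unique(labels[strong])
    keep_ids = keep_ids[keep_ids > 0]
    edges = np.isin(labels, keep_ids)
    return BinaryMask(np.where(edges, np.uint8(255), np.uint8(0)))
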