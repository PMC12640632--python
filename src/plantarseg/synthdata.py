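"""Synthetic plantar pressure images with programmatic ground truth.

The generator composes a footprint from parametric lobes: an elliptical
forefoot pad and heel, a midfoot band whose medial cut is controlled by a
``midfoot_contact`` ratio (near-complete contact for low arches, minimal
for high arches), and detached toe blobs.  Heel-tilt types offset the
heel lobe medially or laterally and alter which toes register.

The pressure field mimics a piezoresistive contact scan: contact onset
is a sharp step to a moderate "halo" level, and pressure rises towards
high-load cores under the heel and metatarsals (which reach the contact
rim at the rear of the heel and the front of the forefoot, as they do
under load).  Gaussian sensor noise is added and clipped to 8 bits.

Ground truth is produced by applying the package's own proportional
partition rule to the true noise-free sole geometry, so downstream
evaluation measures how well the full pipeline recovers that geometry
through noise and segmentation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import imageio
from .partition import build_partition
from .types import (
    GroundTruthBox,
    PressureImage,
    REGION_LABELS,
    ValidationError,
)

__all__ = [
    "SynthSpec",
    "SynthSample",
    "generate",
    "generate_dataset",
    "midfoot_contact_fraction",
    "FOOT_TYPES",
    "DEFAULT_MIX",
]

FOOT_TYPES = ("normal", "low_arch", "high_arch", "inward_tilt", "outward_tilt")

#: Midfoot contact ratio per foot type (share of the midfoot band width in
#: contact): slightly curved midfoot for normal feet (~50% contact),
#: near-complete contact for low arches, minimal for high arches.  Tilt
#: types have normal arches; they differ in heel position and toes.
TYPE_MIDFOOT_CONTACT = {
    "normal": 0.50,
    "low_arch": 0.90,
    "high_arch": 0.10,
    "inward_tilt": 0.50,
    "outward_tilt": 0.50,
}

#: Test-set composition: 80 normal footprints and 30 of each abnormal type
#: per 200, scaled proportionally for other dataset sizes.
DEFAULT_MIX = {
    "normal": 80,
    "low_arch": 30,
    "high_arch": 30,
    "inward_tilt": 30,
    "outward_tilt": 30,
}

# pressure levels (kPa == intensity counts)
_P_HALO = 120.0  # contact onset level at the footprint rim
_P_CORE = 235.0  # peak load under heel / metatarsal cores
_P_ARCH = 165.0  # lateral arch load core
_CORE_SLOPE = 18.0  # kPa per px falloff outside a core
_ARCH_SLOPE = 10.0


@dataclass(frozen=True)
class SynthSpec:
    foot_type: str = "normal"
    side: str = "left"
    image_size: tuple[int, int] = (700, 700)  # (width, height)
    foot_length: int = 420
    foot_width: float | None = None  # default 0.38 * foot_length
    midfoot_contact: float | None = None  # default per foot type
    completeness: str = "complete"  # complete | missing_toes | incomplete
    noise_sd: float = 2.0
    seed: int = 0
    center_x: float | None = None  # default: quarter-line of the side's half
    top_y: float | None = None

    def __post_init__(self) -> None:
        if self.foot_type not in FOOT_TYPES:
            raise ValidationError(f"unknown foot type {self.foot_type!r}")
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be left/right, got {self.side!r}")
        if self.completeness not in ("complete", "missing_toes", "incomplete"):
            raise ValidationError(f"unknown completeness {self.completeness!r}")
        mc = self.resolved_midfoot_contact
        if not 0.0 <= mc <= 1.0:
            raise ValidationError(f"midfoot_contact must be in [0, 1], got {mc}")

    @property
    def resolved_midfoot_contact(self) -> float:
        if self.midfoot_contact is not None:
            return self.midfoot_contact
        return TYPE_MIDFOOT_CONTACT[self.foot_type]

    @property
    def resolved_width(self) -> float:
        return self.foot_width if self.foot_width is not None else 0.38 * self.foot_length


@dataclass
class SynthSample:
    image: PressureImage
    gt_boxes: list[GroundTruthBox]
    gt_mask: np.ndarray  # 0 background, 1..4 per REGION_LABELS
    sole_mask: np.ndarray  # true noise-free sole foreground (bool)
    meta: dict = field(default_factory=dict)


def _ellipse(xx: np.ndarray, yy: np.ndarray, cx: float, cy: float, a: float, b: float) -> np.ndarray:
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _sole_geometry(spec: SynthSpec) -> dict:
    """Continuous-parameter description of the sole, in left-foot canonical
    form (medial side towards +x); the right foot is mirrored afterwards."""
    L = float(spec.foot_length)
    W = float(spec.resolved_width)
    img_w, img_h = spec.image_size
    cx_final = spec.center_x if spec.center_x is not None else (
        img_w * 0.27 if spec.side == "left" else img_w * 0.73
    )
    # the foot is rasterised in left-foot canonical form and mirrored for
    # the right side, so reflect the requested centre into canonical coords
    cx = cx_final if spec.side == "left" else (img_w - 1) - cx_final
    top = spec.top_y if spec.top_y is not None else (img_h - L) / 2.0

    # heel-tilt offset: calcaneus deviates medially (inward) or laterally
    # (outward); for the canonical left foot the medial side is +x
    tilt = 0.0
    if spec.foot_type == "inward_tilt":
        tilt = 0.10 * W
    elif spec.foot_type == "outward_tilt":
        tilt = -0.10 * W
    return {"L": L, "W": W, "cx": cx, "top": top, "tilt": tilt}


def _rasterize_sole(spec: SynthSpec) -> tuple[np.ndarray, dict]:
    """True sole mask (toes excluded) plus the core regions of the
    pressure model, all in canonical left-foot orientation."""
    g = _sole_geometry(spec)
    L, W, cx, top, tilt = g["L"], g["W"], g["cx"], g["top"], g["tilt"]
    img_w, img_h = spec.image_size
    m = spec.resolved_midfoot_contact

    if top < 6 or top + L > img_h - 6:
        raise ValidationError(
            f"foot of length {L} does not fit image height {img_h} with margin"
        )
    # in canonical (left-foot) coordinates both sides must fit the left half
    half = img_w / 2
    lat_edge = cx - 0.55 * W
    med_edge = cx + 0.55 * W + abs(tilt)
    if lat_edge < 2 or med_edge >= half - 1:
        raise ValidationError("foot does not fit inside its image half")

    yy, xx = np.mgrid[0:img_h, 0:img_w]
    yy = yy.astype(np.float64)
    xx = xx.astype(np.float64)

    # forefoot pad: top pole at `top`
    fore_c = (cx, top + 0.18 * L)
    fore_ab = (0.50 * W, 0.18 * L)
    fore = _ellipse(xx, yy, *fore_c, *fore_ab)
    # heel: bottom pole at top + L
    heel_c = (cx + tilt, top + 0.83 * L)
    heel_ab = (0.40 * W, 0.17 * L)
    heel = _ellipse(xx, yy, *heel_c, *heel_ab)

    # midfoot band between the pads: lateral boundary nearly straight,
    # medial boundary cut inward by (1 - midfoot_contact)
    t0, t1 = top + 0.25 * L, top + 0.78 * L
    t = np.clip((yy - t0) / (t1 - t0), 0.0, 1.0)
    x_lat = (cx - 0.50 * W) * (1 - t) + (cx + tilt - 0.40 * W) * t
    base = (0.95 * W) * (1 - t) + (0.80 * W) * t
    # contact profile: ~flat at midfoot_contact over the band interior,
    # blending to full width at the pad junctions
    bump = np.sin(np.pi * t) ** 0.4
    width = base * (1.0 - (1.0 - m) * bump)
    band = (yy >= t0) & (yy <= t1) & (xx >= x_lat) & (xx <= x_lat + width)

    sole = fore | heel | band
    # round the concave pad/band junctions (real contact outlines have no
    # sharp re-entrant corners)
    r = 5
    disk = (np.hypot(*np.mgrid[-r : r + 1, -r : r + 1]) <= r)
    sole = ndimage.binary_closing(sole, structure=disk)

    if spec.completeness == "incomplete":
        rng = np.random.default_rng(spec.seed + 101)
        gap_top = top + rng.uniform(0.35, 0.55) * L
        gap = (yy >= gap_top) & (yy <= gap_top + 0.12 * L)
        sole &= ~gap

    # load cores: scaled ellipses shifted so they reach the contact rim at
    # the rear of the heel and the front of the forefoot
    heel_core = _ellipse(
        xx, yy, heel_c[0], heel_c[1] + 0.2 * heel_ab[1], 0.8 * heel_ab[0], 0.8 * heel_ab[1]
    )
    fore_core = _ellipse(
        xx, yy, fore_c[0], fore_c[1] - 0.2 * fore_ab[1], 0.8 * fore_ab[0], 0.8 * fore_ab[1]
    )
    arch_zone = (yy >= top + 0.32 * L) & (yy <= top + 0.68 * L)
    return sole, {
        "cores": (heel_core | fore_core) & sole,
        "arch_zone": arch_zone,
        "geom": g,
    }


def _toe_blobs(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Detached toe blobs above the forefoot (canonical left foot).

    Inward heel tilt drops the hallux; outward heel tilt keeps only the
    hallux."""
    g = _sole_geometry(spec)
    L, W, cx, top = g["L"], g["W"], g["cx"], g["top"]
    img_w, img_h = spec.image_size
    yy, xx = np.mgrid[0:img_h, 0:img_w]
    blobs = np.zeros((img_h, img_w), dtype=bool)
    if spec.completeness == "missing_toes":
        return blobs
    # hallux on the medial (+x) side, smaller toes towards lateral
    toe_y = top - 0.045 * L
    positions = np.linspace(cx + 0.36 * W, cx - 0.42 * W, 5)  # hallux first
    radii = np.array([0.040, 0.028, 0.026, 0.024, 0.022]) * L
    keep = np.ones(5, dtype=bool)
    if spec.foot_type == "inward_tilt":
        keep[0] = False  # toe area may exclude the hallux
    elif spec.foot_type == "outward_tilt":
        keep[1:] = False  # toe area may show only the hallux
    for i in range(5):
        if not keep[i]:
            continue
        r = radii[i] * rng.uniform(0.9, 1.1)
        ty = toe_y - (0.02 * L if i else 0.0) + rng.uniform(-2, 2)
        blobs |= ((xx - positions[i]) ** 2 + (yy - ty) ** 2) <= r**2
    return blobs


def _pressure_field(
    sole: np.ndarray, parts: dict, toes: np.ndarray, spec: SynthSpec, rng: np.random.Generator
) -> np.ndarray:
    cores = parts["cores"]
    arch_zone = parts["arch_zone"]
    p = np.zeros(sole.shape, dtype=np.float64)
    p[sole] = _P_HALO
    if cores.any():
        d_core = ndimage.distance_transform_edt(~cores)
        p_core = _P_CORE - _CORE_SLOPE * d_core
        np.maximum(p, np.where(sole, p_core, 0.0), out=p)
    # lateral arch load: deep-contact pixels of the midfoot zone
    dt = ndimage.distance_transform_edt(sole)
    arch_core = sole & arch_zone & (dt >= 6.0) & ~cores
    if arch_core.any():
        d_arch = ndimage.distance_transform_edt(~arch_core)
        p_arch = _P_ARCH - _ARCH_SLOPE * d_arch
        np.maximum(p, np.where(sole, p_arch, 0.0), out=p)
    p[toes] = 150.0
    if spec.noise_sd > 0:
        p = p + rng.normal(0.0, spec.noise_sd, size=p.shape)
    return np.clip(np.rint(p), 0, 255).astype(np.uint8)


def generate(spec: SynthSpec) -> SynthSample:
    """Generate one footprint with its programmatic ground truth.

    Deterministic: the same spec (including seed) yields bit-identical
    images.  Ground-truth boxes come from the proportional partition of
    the true noise-free sole mask; toes are excluded from that geometry
    just as the pipeline's area filter excludes them downstream.
    """
    rng = np.random.default_rng(spec.seed)
    sole, parts = _rasterize_sole(spec)
    toes = _toe_blobs(spec, rng)
    pixels = _pressure_field(sole, parts, toes, spec, rng)

    if spec.side == "right":  # canonical form is a left foot: mirror
        sole = sole[:, ::-1]
        pixels = pixels[:, ::-1]
        toes = toes[:, ::-1]

    ys, xs = np.nonzero(sole)
    points = np.column_stack([xs, ys])
    part = build_partition(points, spec.side, img_width=spec.image_size[0])
    gt_boxes = part.as_ground_truth()

    gt_mask = np.zeros(sole.shape, dtype=np.uint8)
    for i, lbl in enumerate(REGION_LABELS, start=1):
        b = part.boxes[lbl]
        region = np.zeros(sole.shape, dtype=bool)
        region[b.y : b.y2, b.x : b.x2] = True
        gt_mask[region & sole] = i

    meta = {
        "spec": spec,
        "foot_length_px": part.foot_length,
        "y_min": part.y_min,
        "y_max": part.y_max,
        "bands": part.bands,
    }
    return SynthSample(
        image=PressureImage(pixels),
        gt_boxes=gt_boxes,
        gt_mask=gt_mask,
        sole_mask=sole,
        meta=meta,
    )


def midfoot_contact_fraction(sample: SynthSample) -> float:
    """Midfoot contact level of the true sole mask: foreground area in the
    midfoot band divided by (band height x overall foot width), i.e. the
    share of the foot's width that stays in contact through the arch."""
    boxes = {b.region_label: b.box for b in sample.gt_boxes}
    b = boxes["midfoot"]
    ys, xs = np.nonzero(sample.sole_mask)
    foot_width = int(xs.max()) - int(xs.min()) + 1
    band = sample.sole_mask[b.y : b.y2, :]
    return float(band.sum()) / float(b.h * foot_width)


def _apportion(n: int, mix: dict[str, int]) -> dict[str, int]:
    """Largest-remainder apportionment of ``n`` samples to the mix weights."""
    total = sum(mix.values())
    exact = {k: n * v / total for k, v in mix.items()}
    counts = {k: int(np.floor(e)) for k, e in exact.items()}
    short = n - sum(counts.values())
    order = sorted(mix, key=lambda k: (-(exact[k] - counts[k]), list(mix).index(k)))
    for k in order[:short]:
        counts[k] += 1
    return counts


def generate_dataset(
    n: int,
    out_dir: str | Path,
    mix: dict[str, int] | None = None,
    seed: int = 0,
    image_size: tuple[int, int] = (700, 700),
    include_incomplete: bool = False,
) -> list[dict]:
    """Generate ``n`` footprints (one per image) with ground truth files.

    Writes, per sample, ``<name>.png`` (the pressure image),
    ``<name>.txt`` (YOLO boxes), ``<name>.json`` (JSON dialect boxes),
    plus a ``manifest.csv`` listing file, foot type, side and
    normal/abnormal group.  The composition follows ``mix`` (default
    80 normal : 30 per abnormal type per 200) by largest-remainder
    apportionment.  Fully reproducible from ``seed``.
    """
    if n < 5:
        raise ValidationError(f"need n >= 5 to cover the five foot types, got {n}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mix = mix or DEFAULT_MIX
    counts = _apportion(n, mix)
    rng = np.random.default_rng(seed)

    manifest: list[dict] = []
    idx = 0
    for foot_type in mix:
        for _ in range(counts[foot_type]):
            side = "left" if idx % 2 == 0 else "right"
            L = int(rng.uniform(0.9, 1.06) * 420 * image_size[1] / 700)
            spec = SynthSpec(
                foot_type=foot_type,
                side=side,
                image_size=image_size,
                foot_length=L,
                foot_width=float(L * rng.uniform(0.36, 0.40)),
                midfoot_contact=float(
                    np.clip(
                        TYPE_MIDFOOT_CONTACT[foot_type] + rng.uniform(-0.06, 0.06),
                        0.03,
                        0.97,
                    )
                ),
                completeness=(
                    "incomplete"
                    if include_incomplete and rng.random() < 0.1
                    else "complete"
                ),
                noise_sd=2.0,
                seed=int(rng.integers(0, 2**31 - 1)),
                center_x=image_size[0] * (0.27 if side == "left" else 0.73)
                + float(rng.uniform(-10, 10)),
                top_y=(image_size[1] - L) / 2.0 + float(rng.uniform(-15, 15)),
            )
            sample = generate(spec)
            name = f"{idx:04d}_{foot_type}_{side}"
            imageio.write_image(sample.image, out_dir / f"{name}.png")
            imageio.write_ground_truth_yolo(
                sample.gt_boxes, out_dir / f"{name}.txt", *image_size
            )
            imageio.write_ground_truth_json(
                sample.gt_boxes, out_dir / f"{name}.json", image_name=f"{name}.png"
            )
            manifest.append(
                {
                    "file": f"{name}.png",
                    "foot_type": foot_type,
                    "side": side,
                    "group": "normal" if foot_type == "normal" else "abnormal",
                    "completeness": spec.completeness,
                    "seed": spec.seed,
                }
            )
            idx += 1

    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(manifest[0].keys()))
        writer.writeheader()
        writer.writerows(manifest)
    return manifest
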