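"""Image and annotation I/O.

Pressure images travel as 8-bit single-channel PNG or PGM (P5) files and
round-trip bit-exactly.  Ground-truth region boxes are read and written
either as YOLO-style text (``class_id cx cy w h``, normalised to the
image size) or as a small JSON dialect
``{"image": ..., "boxes": [{"side", "label", "x", "y", "w", "h"}]}``.
A pseudo-colour renderer maps intensity through a perceptually monotone
colormap, optionally with a kPa colorbar.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
from PIL import Image

from .types import (
    REGION_LABELS,
    SIDES,
    FormatError,
    GroundTruthBox,
    PressureImage,
    Rect,
    SchemaError,
    ValidationError,
)

__all__ = [
    "read_image",
    "write_image",
    "write_pseudocolor",
    "read_ground_truth",
    "write_ground_truth_yolo",
    "write_ground_truth_json",
    "YOLO_CLASS_MAP",
]

log = logging.getLogger(__name__)

#: YOLO class id <-> (side, region label).  Ids 0-3 left, 4-7 right,
#: regions in toe-to-heel order.
YOLO_CLASS_MAP: dict[int, tuple[str, str]] = {
    side_i * 4 + lbl_i: (side, lbl)
    for side_i, side in enumerate(SIDES)
    for lbl_i, lbl in enumerate(REGION_LABELS)
}
_YOLO_CLASS_INV = {v: k for k, v in YOLO_CLASS_MAP.items()}

#: Decimal places used when writing normalised YOLO coordinates.
YOLO_PRECISION = 6


def read_image(path: str | Path) -> PressureImage:
    """Read a pressure image from PNG or PGM.

    8-bit single-channel data is preserved bit-exactly.  Multi-channel
    images are accepted but converted to luminance with a warning; bit
    depths other than 8 are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = Image.open(path)
    if img.mode in ("I", "I;16", "I;16B", "I;16L", "F"):
        raise FormatError(f"unsupported bit depth/mode {img.mode!r} in {path} (need 8-bit)")
    if img.mode != "L":
        log.warning("image %s has mode %s; converting to luminance", path, img.mode)
        img = img.convert("L")
    return PressureImage(np.asarray(img, dtype=np.uint8))


def write_image(img: PressureImage, path: str | Path) -> Path:
    """Write an 8-bit single-channel PNG or PGM (chosen by file suffix)."""
    path = Path(path)
    Image.fromarray(img.pixels, mode="L").save(path)
    return path


def write_pseudocolor(
    img: PressureImage, path: str | Path, colorbar: bool = False
) -> Path:
    """Render the pressure map pseudo-coloured to an RGB PNG.

    Colour is a monotone function of intensity (matplotlib's viridis,
    256 distinct entries).  With ``colorbar=True`` a legend in kPa
    (``intensity * pressure_scale``) is embedded via matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    if colorbar:
        from matplotlib.colors import ListedColormap

        cmap = ListedColormap(pseudocolor_lut() / 255.0)
        fig, ax = plt.subplots(figsize=(6, 6))
        im = ax.imshow(img.pixels, cmap=cmap, vmin=0, vmax=255)
        cb = fig.colorbar(im, ax=ax, fraction=0.046)
        ticks = cb.get_ticks()
        cb.set_ticks(ticks)
        cb.set_ticklabels([f"{t * img.pressure_scale:.0f}" for t in ticks])
        cb.set_label("pressure (kPa)")
        ax.set_axis_off()
        fig.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(fig)
    else:
        rgb = pseudocolor_lut()[img.pixels]
        Image.fromarray(rgb, mode="RGB").save(path)
    return path


def pseudocolor_lut() -> np.ndarray:
    """The 256x3 uint8 lookup table used by :func:`write_pseudocolor`.

    A cold-to-warm ramp (blue -> green/yellow -> red) like the scanner's
    live display: red rises and blue falls strictly with intensity, so
    the mapping is monotone and all 256 entries are distinct."""
    i = np.arange(256)
    r = i
    g = np.clip(np.minimum(2 * i, 2 * (255 - i)), 0, 255)
    b = 255 - i
    return np.stack([r, g, b], axis=1).astype(np.uint8)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def _check_bounds(box: Rect, img_width: int, img_height: int) -> Rect:
    if box.x < 0 or box.y < 0 or box.x2 > img_width or box.y2 > img_height:
        raise ValidationError(
            f"box {box.as_dict()} exceeds image bounds {img_width}x{img_height}"
        )
    return box


def read_ground_truth(
    path: str | Path, img_width: int, img_height: int
) -> list[GroundTruthBox]:
    """Read region annotations from YOLO text or the JSON dialect.

    YOLO lines are ``class_id cx cy w h`` with coordinates normalised to
    the image size; they are converted to absolute half-open pixel boxes.
    The format is chosen by file suffix (``.json`` vs anything else).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_gt_json(path, img_width, img_height)
    return _read_gt_yolo(path, img_width, img_height)


def _read_gt_yolo(path: Path, img_width: int, img_height: int) -> list[GroundTruthBox]:
    boxes: list[GroundTruthBox] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 5:
            raise SchemaError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
        try:
            cls = int(fields[0])
            cx, cy, w, h = (float(f) for f in fields[1:])
        except ValueError as exc:
            raise SchemaError(f"{path}:{lineno}: {exc}") from exc
        if cls not in YOLO_CLASS_MAP:
            raise SchemaError(f"{path}:{lineno}: unknown class id {cls}")
        side, label = YOLO_CLASS_MAP[cls]
        px_w = round(w * img_width)
        px_h = round(h * img_height)
        px_x = round(cx * img_width - px_w / 2)
        px_y = round(cy * img_height - px_h / 2)
        box = _check_bounds(Rect(px_x, px_y, px_w, px_h), img_width, img_height)
        boxes.append(GroundTruthBox(side, label, box))
    return boxes


def _read_gt_json(path: Path, img_width: int, img_height: int) -> list[GroundTruthBox]:
    data = json.loads(path.read_text())
    if not isinstance(data, dict) or "boxes" not in data:
        raise SchemaError(f"{path}: expected an object with a 'boxes' list")
    boxes: list[GroundTruthBox] = []
    for i, entry in enumerate(data["boxes"]):
        try:
            side = entry["side"]
            label = entry["label"]
            rect = Rect(int(entry["x"]), int(entry["y"]), int(entry["w"]), int(entry["h"]))
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"{path}: malformed box entry {i}: {exc}") from exc
        _check_bounds(rect, img_width, img_height)
        boxes.append(GroundTruthBox(side, label, rect))
    return boxes


def write_ground_truth_yolo(
    boxes: list[GroundTruthBox], path: str | Path, img_width: int, img_height: int
) -> Path:
    """Write YOLO-style annotations, normalised coordinates quantised to
    6 decimals (stable round-trips for image sizes up to ~10^5 px)."""
    path = Path(path)
    lines = []
    for b in boxes:
        cls = _YOLO_CLASS_INV[(b.foot_side, b.region_label)]
        cx = (b.box.x + b.box.w / 2) / img_width
        cy = (b.box.y + b.box.h / 2) / img_height
        w = b.box.w / img_width
        h = b.box.h / img_height
        lines.append(
            f"{cls} {cx:.{YOLO_PRECISION}f} {cy:.{YOLO_PRECISION}f} "
            f"{w:.{YOLO_PRECISION}f} {h:.{YOLO_PRECISION}f}"
        )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def write_ground_truth_json(
    boxes: list[GroundTruthBox], path: str | Path, image_name: str = ""
) -> Path:
    path = Path(path)
    payload = {
        "image": image_name,
        "boxes": [
            {"side": b.foot_side, "label": b.region_label, **b.box.as_dict()}
            for b in boxes
        ],
    }
    path.write_text(json.dumps(payload, indent=1))
    return path
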