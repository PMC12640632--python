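"""End-to-end pipeline: segment -> trace -> filter -> assign -> partition.

Runs one of the three segmentation backends on each image, extracts and
area-filters contours, assigns them to the left/right foot by the image
midline, and partitions each detected foot into the four anatomical
region boxes.  Per-image failures (no surviving contour, incomplete
foot) are recorded and never abort a batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import contours as contours_mod
from . import evaluation, imageio, segmentation
from .partition import build_partition, collect_foot_points
from .types import (
    GroundTruthBox,
    IncompleteFootError,
    MissingFootError,
    PressureImage,
    ValidationError,
)

__all__ = ["PipelineConfig", "run_on_image", "run_pipeline", "compare_methods", "METHODS"]

log = logging.getLogger(__name__)

METHODS = ("threshold", "splitmerge", "canny")


@dataclass
class PipelineConfig:
    """Everything that parameterises one pipeline run.

    Defaults follow the recommended operating point: Canny with the
    (300, 600) double-threshold pair, which keeps only the outer foot
    contour, and the 6000 px^2 contour area filter."""

    method: str = "canny"
    threshold_params: segmentation.ThresholdParams = field(
        default_factory=lambda: segmentation.PRESETS["threshold"]["default"]
    )
    splitmerge_params: segmentation.SplitMergeParams = field(
        default_factory=lambda: segmentation.PRESETS["splitmerge"]["default"]
    )
    canny_params: segmentation.CannyParams = field(
        default_factory=lambda: segmentation.PRESETS["canny"]["outer"]
    )
    min_area: float = contours_mod.DEFAULT_MIN_AREA
    band_proportions: tuple[float, float, float] = (0.3, 0.3, 0.4)
    iou_thresholds: tuple[float, ...] = evaluation.DEFAULT_IOU_THRESHOLDS

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"method must be one of {METHODS}, got {self.method!r}")
        if abs(sum(self.band_proportions) - 1.0) > 1e-9:
            raise ValidationError(
                f"band proportions must sum to 1, got {self.band_proportions}"
            )


def segment_image(img: PressureImage, cfg: PipelineConfig):
    if cfg.method == "threshold":
        return segmentation.threshold_simple(img, cfg.threshold_params)
    if cfg.method == "splitmerge":
        return segmentation.split_merge(img, cfg.splitmerge_params)
    return segmentation.canny(img, cfg.canny_params)


def run_on_image(img: PressureImage, cfg: PipelineConfig) -> dict:
    """Run the full pipeline on one image.

    Returns ``{"boxes": [GroundTruthBox-like predictions], "failures":
    [msgs], "counts": {...stage counters}}``.  Sides with no surviving
    contour or an incomplete foot are reported in ``failures``.
    """
    mask = segment_image(img, cfg)
    cs = contours_mod.trace_contours(mask)
    kept = contours_mod.filter_by_area(cs, cfg.min_area)
    regions = contours_mod.assign_regions(kept, img.width)
    counts = {
        "contours_found": len(cs),
        "contours_kept": len(kept),
        "feet_detected": len({r.side for r in regions}),
    }
    boxes: list[GroundTruthBox] = []
    failures: list[str] = []
    for side in sorted({r.side for r in regions}):
        try:
            pts = collect_foot_points(kept, regions, side)
            part = build_partition(pts, side, img.width)
            boxes.extend(part.as_ground_truth())
        except (MissingFootError, IncompleteFootError, ValidationError) as exc:
            failures.append(f"{side}: {exc}")
    if not regions:
        failures.append("no contour survived filtering")
    log.info(
        "pipeline(%s): %d contours, %d kept, %d feet, %d failures",
        cfg.method, counts["contours_found"], counts["contours_kept"],
        counts["feet_detected"], len(failures),
    )
    return {"boxes": boxes, "failures": failures, "counts": counts}


def run_pipeline(image_paths: list[str | Path], cfg: PipelineConfig) -> dict:
    """Batch run over image files; deterministic given config and inputs.

    Returns ``{"predictions": {name: [box dicts]}, "failures": {name:
    [msgs]}}`` with boxes as plain dicts ready for JSON."""
    predictions: dict[str, list[dict]] = {}
    failures: dict[str, list[str]] = {}
    for p in image_paths:
        p = Path(p)
        img = imageio.read_image(p)
        res = run_on_image(img, cfg)
        predictions[p.name] = [
            {"side": b.foot_side, "label": b.region_label, **b.box.as_dict()}
            for b in res["boxes"]
        ]
        if res["failures"]:
            failures[p.name] = res["failures"]
    return {"predictions": predictions, "failures": failures}


def evaluate_dataset(
    samples: list[dict],
    cfg: PipelineConfig,
) -> evaluation.EvalReport:
    """Score pipeline predictions against ground truth.

    ``samples`` entries: ``{"image": PressureImage, "gt":
    [GroundTruthBox], "group": "normal"|"abnormal"}``.  Feet that fail
    the pipeline contribute IoU 0 through their unmatched ground truths
    being scored as misses at every threshold (false negatives with IoU
    0 in the mean).
    """
    per_image = []
    for s in samples:
        res = run_on_image(s["image"], cfg)
        cells = evaluation.match_boxes(res["boxes"], s["gt"])
        # score unmatched ground truths as IoU-0 detections so that mean
        # IoU reflects outright failures as zeros
        for cell in cells.values():
            if cell.false_negatives:
                cell.ious.extend([0.0] * cell.false_negatives)
                cell.false_negatives = 0
        per_image.append({"group": s["group"], "cells": cells})
    return evaluation.grouped_report(per_image, cfg.iou_thresholds)


def compare_methods(
    samples: list[dict],
    base_cfg: PipelineConfig | None = None,
    methods: tuple[str, ...] = METHODS,
) -> dict[str, evaluation.EvalReport]:
    """Run the requested methods over the same samples and report each.

    The result is ordered like ``methods``; use the reports' per-cell
    means to build the side x region comparison table."""
    base_cfg = base_cfg or PipelineConfig()
    out: dict[str, evaluation.EvalReport] = {}
    for m in methods:
        cfg = PipelineConfig(
            method=m,
            threshold_params=base_cfg.threshold_params,
            splitmerge_params=base_cfg.splitmerge_params,
            canny_params=base_cfg.canny_params,
            min_area=base_cfg.min_area,
            band_proportions=base_cfg.band_proportions,
            iou_thresholds=base_cfg.iou_thresholds,
        )
        out[m] = evaluate_dataset(samples, cfg)
    return out


def comparison_table(reports: dict[str, evaluation.EvalReport]):
    """Side x region rows, (method x {IoU, mAP}) columns, as a DataFrame."""
    import pandas as pd

    keys = sorted({k for r in reports.values() for k in r.per_region})
    rows = []
    for side, label in keys:
        row: dict[str, object] = {"side": side, "region": label}
        for m, rep in reports.items():
            cell = rep.per_region.get((side, label), {})
            row[f"{m}_iou"] = round(cell.get("mean_iou", float("nan")), 4)
            row[f"{m}_ap"] = round(cell.get("ap", float("nan")), 4)
        rows.append(row)
    return pd.DataFrame(rows)
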