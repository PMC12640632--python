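"""Scoring of predicted region boxes against ground truth.

Metrics follow standard object-detection practice adapted to a
single-proposal detector (the pipeline emits exactly one box per region
per foot): pixel-exact IoU on half-open boxes, Average Precision over a
sweep of IoU thresholds (0.50:0.05:0.95 by default, overridable to a
single threshold), and mAP as the mean AP over region cells.  Reports
use a two-step average — mean within the normal and abnormal groups
first, then the unweighted mean of the two group means — with pooled
means also included for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import GroundTruthBox, Rect, ValidationError

__all__ = [
    "iou",
    "performance_band",
    "average_precision",
    "grouped_report",
    "EvalReport",
    "DEFAULT_IOU_THRESHOLDS",
]

#: Default AP protocol: IoU thresholds 0.50, 0.55, ..., 0.95.
DEFAULT_IOU_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


def iou(a: Rect, b: Rect) -> float:
    """Intersection over union of two boxes (pixel counts, half-open)."""
    inter = a.intersection_area(b)
    union = a.area + b.area - inter
    return inter / union


def performance_band(value: float) -> str:
    """Qualitative band for an IoU value: poor below 0.6, good in
    [0.6, 0.90), excellent at or above 0.90."""
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"IoU must lie in [0, 1], got {value}")
    if value < 0.6:
        return "poor"
    if value < 0.90:
        return "good"
    return "excellent"


@dataclass
class CellScores:
    """Per (side, label) cell: one IoU per scored footprint."""

    ious: list[float] = field(default_factory=list)
    false_negatives: int = 0  # ground-truth boxes with no prediction


def match_boxes(
    preds: list[GroundTruthBox], gts: list[GroundTruthBox]
) -> dict[tuple[str, str], CellScores]:
    """Match same-(side, label) predicted and ground-truth boxes of one image.

    Each cell holds at most one box on either side (single-proposal
    detector).  A prediction without a ground-truth partner scores IoU 0
    (false positive at every threshold); a ground truth without a
    prediction counts as a false negative; cells absent from both are
    skipped.
    """
    out: dict[tuple[str, str], CellScores] = {}
    pmap = {(p.foot_side, p.region_label): p for p in preds}
    gmap = {(g.foot_side, g.region_label): g for g in gts}
    for key in set(pmap) | set(gmap):
        cell = out.setdefault(key, CellScores())
        if key in pmap and key in gmap:
            cell.ious.append(iou(pmap[key].box, gmap[key].box))
        elif key in pmap:
            cell.ious.append(0.0)
        else:
            cell.false_negatives += 1
    return out


def average_precision(
    ious: list[float],
    false_negatives: int = 0,
    iou_thresholds: tuple[float, ...] = DEFAULT_IOU_THRESHOLDS,
) -> float:
    """AP for one region cell from its per-footprint IoUs.

    At each threshold ``t`` a prediction is a true positive iff its IoU
    >= t; with one proposal per instance, precision = TP / (TP + FP)
    where every non-TP prediction is an FP, and missed ground truths
    enter the denominator through recall.  AP is the mean over thresholds
    of precision * (recall adjustment collapses to TP / total instances
    when each instance gets exactly one prediction or none).
    """
    if not ious and false_negatives == 0:
        raise ValidationError("no scored instances")
    arr = np.asarray(ious, dtype=np.float64)
    total = len(arr) + false_negatives
    precisions = [float(np.count_nonzero(arr >= t)) / total for t in iou_thresholds]
    return float(np.mean(precisions))


@dataclass
class EvalReport:
    """Aggregated scores: per-cell mean IoU and AP, mAP, bands, group means."""

    per_region: dict[tuple[str, str], dict[str, float]]
    map_score: float
    band: dict[tuple[str, str], str]
    group_means: dict[str, dict[str, float]]
    pooled: dict[tuple[str, str], dict[str, float]]
    iou_thresholds: tuple[float, ...]
    warnings: list[str] = field(default_factory=list)

    @property
    def min_mean_iou(self) -> float:
        return min(v["mean_iou"] for v in self.per_region.values())

    @property
    def min_ap(self) -> float:
        return min(v["ap"] for v in self.per_region.values())

    @property
    def mean_iou(self) -> float:
        return float(np.mean([v["mean_iou"] for v in self.per_region.values()]))


def grouped_report(
    per_image: list[dict],
    iou_thresholds: tuple[float, ...] = DEFAULT_IOU_THRESHOLDS,
) -> EvalReport:
    """Build an :class:`EvalReport` from per-image match results.

    ``per_image`` entries are ``{"group": "normal"|"abnormal",
    "cells": {(side, label): CellScores}}`` as produced by
    :func:`match_boxes`.  Final per-cell metrics are the unweighted mean
    of the normal-group and abnormal-group means; if one group is empty
    the other group's mean is used and a warning is recorded.
    """
    groups = ("normal", "abnormal")
    warnings: list[str] = []
    # gather per group, per cell
    acc: dict[str, dict[tuple[str, str], CellScores]] = {g: {} for g in groups}
    for item in per_image:
        g = item["group"]
        if g not in acc:
            raise ValidationError(f"group must be normal/abnormal, got {g!r}")
        for key, cell in item["cells"].items():
            tgt = acc[g].setdefault(key, CellScores())
            tgt.ious.extend(cell.ious)
            tgt.false_negatives += cell.false_negatives

    keys = sorted({k for g in groups for k in acc[g]})
    per_region: dict[tuple[str, str], dict[str, float]] = {}
    pooled: dict[tuple[str, str], dict[str, float]] = {}
    group_means: dict[str, dict[str, float]] = {g: {} for g in groups}

    for key in keys:
        cell_metrics = {}
        for g in groups:
            cell = acc[g].get(key)
            if cell is None or (not cell.ious and cell.false_negatives == 0):
                continue
            vals = cell.ious or [0.0]
            cell_metrics[g] = {
                "mean_iou": float(np.mean(vals)),
                "ap": average_precision(cell.ious, cell.false_negatives, iou_thresholds),
            }
        if not cell_metrics:
            continue
        if len(cell_metrics) == 1:
            g_present = next(iter(cell_metrics))
            warnings.append(
                f"cell {key}: only the {g_present} group has samples; "
                "final value equals that group's mean"
            )
        per_region[key] = {
            "mean_iou": float(np.mean([m["mean_iou"] for m in cell_metrics.values()])),
            "ap": float(np.mean([m["ap"] for m in cell_metrics.values()])),
        }
        # pooled (weighted) means for transparency
        all_ious = [v for g in groups if acc[g].get(key) for v in acc[g][key].ious]
        all_fn = sum(acc[g][key].false_negatives for g in groups if acc[g].get(key))
        pooled[key] = {
            "mean_iou": float(np.mean(all_ious)) if all_ious else 0.0,
            "ap": average_precision(all_ious, all_fn, iou_thresholds),
        }
        for g, m in cell_metrics.items():
            group_means[g][f"{key[0]}/{key[1]}/mean_iou"] = m["mean_iou"]
            group_means[g][f"{key[0]}/{key[1]}/ap"] = m["ap"]

    if not per_region:
        raise ValidationError("no scorable cells in the evaluation input")
    map_score = float(np.mean([v["ap"] for v in per_region.values()]))
    band = {k: performance_band(v["mean_iou"]) for k, v in per_region.items()}
    return EvalReport(
        per_region=per_region,
        map_score=map_score,
        band=band,
        group_means=group_means,
        pooled=pooled,
        iou_thresholds=tuple(iou_thresholds),
        warnings=warnings,
    )
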