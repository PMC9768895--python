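"""Segmentation evaluation: confusion counts, IoU (Jaccard index), and the
accuracy / specificity / sensitivity / precision / F1 family, with per-zone
aggregation.

Metrics with a zero denominator are reported as NaN ("undefined"), never as
0 — all-negative slices occur routinely in amyloid-negative cases and a
silent 0 would poison zone averages.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "iou_metric",
    "dice_metric",
    "report",
    "aggregate_zones",
    "write_reports_csv",
    "write_reports_json",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel- or case-level TP/TN/FP/FN tallies."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """One evaluation row; ``granularity`` records pixel- vs case-level counts."""

    iou: float
    accuracy: float
    specificity: float
    sensitivity: float
    precision: float
    f1: float
    zone_id: str | None = None
    plane: str | None = None
    granularity: str = "pixel"

    def rounded(self) -> dict:
        """Presentation rounding: IoU to 3 d.p., percentages to 1 d.p."""
        out = asdict(self)
        out["iou"] = None if math.isnan(self.iou) else round(self.iou, 3)
        for k in ("accuracy", "specificity", "sensitivity", "precision", "f1"):
            v = out[k]
            out[k] = None if math.isnan(v) else round(100.0 * v, 1)
        return out


def _as_binary(mask) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("masks must be binary")
        arr = arr.astype(bool)
    return arr


def confusion(pred, truth) -> ConfusionCounts:
    """Exact pixel-wise TP/TN/FP/FN tallies between two binary masks."""
    p, t = _as_binary(pred), _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def iou_metric(pred, truth=None) -> float:
    """Intersection over union (Jaccard index), TP / (TP + FP + FN).

    Accepts either a :class:`ConfusionCounts` or a pair of binary masks.
    Empty vs empty is defined as 1 (perfect agreement) with a warning.
    """
    if isinstance(pred, ConfusionCounts):
        c = pred
    else:
        if truth is None:
            raise TypeError("iou_metric needs either counts or (pred, truth)")
        c = confusion(pred, truth)
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn("IoU of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    return c.tp / denom


def dice_metric(pred, truth) -> float:
    """Dice coefficient 2TP / (2TP + FP + FN); cross-check companion to IoU."""
    c = confusion(pred, truth)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2 * c.tp / denom


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def report(
    counts: ConfusionCounts,
    zone_id: str | None = None,
    plane: str | None = None,
    granularity: str = "pixel",
) -> MetricsReport:
    """Full metric family from confusion counts.

    accuracy = (TP+TN)/total, specificity = TN/(TN+FP),
    sensitivity = TP/(TP+FN), precision = TP/(TP+FP),
    F1 = 2·precision·sensitivity/(precision+sensitivity),
    IoU = TP/(TP+FP+FN).  Zero-denominator metrics come back NaN.
    """
    sens = _safe_div(counts.tp, counts.tp + counts.fn)
    prec = _safe_div(counts.tp, counts.tp + counts.fp)
    if math.isnan(sens) or math.isnan(prec) or (prec + sens) == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return MetricsReport(
        iou=_safe_div(counts.tp, counts.tp + counts.fp + counts.fn),
        accuracy=_safe_div(counts.tp + counts.tn, counts.total),
        specificity=_safe_div(counts.tn, counts.tn + counts.fp),
        sensitivity=sens,
        precision=prec,
        f1=f1,
        zone_id=zone_id,
        plane=plane,
        granularity=granularity,
    )


_METRIC_FIELDS = ("iou", "accuracy", "specificity", "sensitivity", "precision", "f1")


def aggregate_zones(reports: list[MetricsReport]) -> dict:
    """Mean, median, min and max of each metric across zone reports.

    NaN (undefined) entries are excluded per metric; a metric undefined in
    every report aggregates to NaN.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    summary: dict[str, dict[str, float]] = {}
    for name in _METRIC_FIELDS:
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            summary[name] = {k: float("nan") for k in ("mean", "median", "min", "max")}
        else:
            summary[name] = {
                "mean": float(vals.mean()),
                "median": float(np.median(vals)),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
    summary["n_reports"] = len(reports)  # type: ignore[assignment]
    return summary


def write_reports_csv(reports: list[MetricsReport], path) -> None:
    """One row per (zone, plane), percentages to 1 d.p., IoU to 3 d.p."""
    path = Path(path)
    rows = [r.rounded() for r in reports]
    fields = ["zone_id", "plane", "granularity", *_METRIC_FIELDS]
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields, extrasaction="ignore")
        writer.writeheader()
        for row in rows:
            writer.writerow({k: ("NA" if row[k] is None else row[k]) for k in fields})


def write_reports_json(reports: list[MetricsReport], path) -> None:
    path = Path(path)
    payload = [r.rounded() for r in reports]
    path.write_text(json.dumps(payload, indent=2))
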