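"""Overlap metrics for binary segmentation masks and per-case reporting.

Eight statistics per (prediction, truth) pair — IoU, Dice, accuracy,
precision, recall, sensitivity, F1, specificity — from pixel-wise
confusion counts with 1 = foreground.  For binary masks several identities
hold exactly and are preserved by construction:

    recall == sensitivity,   f1 == dice,   dice == 2*iou / (1 + iou).

Degenerate 0/0 denominators are made total: a ratio with an empty
denominator is 1.0 when both masks agree the relevant side is empty
(perfect agreement) and 0.0 when only one side is empty.

A report aggregates per-case rows into an arithmetic mean row computed at
full precision; rounding to the 4 decimals used in rendered tables happens
last.  ``compare`` deliberately differences the *rounded* means, the
convention under which published benchmark deltas are reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from ctenhance.errors import ValidationError

__all__ = [
    "METRIC_NAMES",
    "ConfusionCounts",
    "MetricsRow",
    "MetricsReport",
    "confusion_counts",
    "metrics_row",
    "dice_from_iou",
    "aggregate",
    "compare",
    "round4",
    "report_frame",
    "write_report",
    "read_report",
]

METRIC_NAMES = (
    "iou",
    "dice",
    "accuracy",
    "precision",
    "recall",
    "sensitivity",
    "f1",
    "specificity",
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsRow:
    case_id: str
    iou: float
    dice: float
    accuracy: float
    precision: float
    recall: float
    sensitivity: float
    f1: float
    specificity: float

    def values(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class MetricsReport:
    rows: tuple[MetricsRow, ...]
    mean_row: MetricsRow


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if not np.all(np.isin(arr, (0, 1))):
        raise ValidationError(f"{name} mask must contain only 0 and 1")
    return arr.astype(bool)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-wise TP/FP/FN/TN tallies, 1 = positive (foreground)."""
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValidationError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int, other_side_empty: bool) -> float:
    # 0/0: perfect agreement (1.0) when the other mask's relevant side is
    # also empty, total disagreement (0.0) otherwise.
    if den == 0:
        return 1.0 if other_side_empty else 0.0
    return num / den


def metrics_row(counts: ConfusionCounts, case_id: str = "") -> MetricsRow:
    """The eight overlap statistics from one confusion tally."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    total = counts.total
    if total == 0:
        raise ValidationError("cannot score an empty mask pair")
    union = tp + fp + fn
    iou = _ratio(tp, union, other_side_empty=True)  # union empty => both empty
    dice = _ratio(2 * tp, 2 * tp + fp + fn, other_side_empty=True)
    accuracy = (tp + tn) / total
    precision = _ratio(tp, tp + fp, other_side_empty=(fn == 0))
    recall = _ratio(tp, tp + fn, other_side_empty=(fp == 0))
    specificity = _ratio(tn, tn + fp, other_side_empty=(fn == 0))
    # F1 = 2PR/(P+R) reduces to 2tp/(2tp+fp+fn) on counts; evaluating the
    # reduced form keeps the f1 == dice identity exact in floating point.
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, other_side_empty=True)
    return MetricsRow(
        case_id=case_id,
        iou=iou,
        dice=dice,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        sensitivity=recall,
        f1=f1,
        specificity=specificity,
    )


def dice_from_iou(j: float) -> float:
    """Dice coefficient implied by a Jaccard index: D = 2J / (1 + J).

    Useful as a consistency check on reported score tables, since the two
    overlap measures are in exact bijection for binary masks.
    """
    if not 0.0 <= j <= 1.0:
        raise ValidationError(f"IoU must lie in [0, 1], got {j}")
    return 2.0 * j / (1.0 + j)


def aggregate(rows: list[MetricsRow] | tuple[MetricsRow, ...]) -> MetricsReport:
    """Per-metric arithmetic mean across cases, at full precision."""
    if not rows:
        raise ValidationError("cannot aggregate an empty list of rows")
    means = {
        name: float(np.mean([getattr(r, name) for r in rows])) for name in METRIC_NAMES
    }
    return MetricsReport(rows=tuple(rows), mean_row=MetricsRow(case_id="mean", **means))


def round4(x: float) -> float:
    """Decimal round-half-up to 4 places, the table-rendering convention.

    Works on the shortest decimal repr so e.g. 0.98615 -> 0.9862; binary
    ``round`` would give 0.9861 because the float sits a hair below the tie.
    """
    return float(Decimal(repr(float(x))).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


def compare(report_a: MetricsReport, report_b: MetricsReport) -> dict[str, float]:
    """Per-metric mean deltas A - B under the rounded-mean convention.

    Each mean is rounded to 4 decimals before differencing, matching how
    published score tables report their deltas.
    """
    out = {}
    for name in METRIC_NAMES:
        da = round4(getattr(report_a.mean_row, name))
        db = round4(getattr(report_b.mean_row, name))
        out[name] = round4(da - db)
    return out


def report_frame(report: MetricsReport) -> pd.DataFrame:
    """Report as a DataFrame, one row per case plus the mean row."""
    records = [
        {"case_id": r.case_id, **r.values()} for r in (*report.rows, report.mean_row)
    ]
    return pd.DataFrame.from_records(records)


def write_report(report: MetricsReport, path: str | Path) -> None:
    """Write a report as CSV or JSON (by extension), 4-decimal rendering."""
    path = Path(path)
    frame = report_frame(report)
    records = frame.to_dict(orient="records")
    for rec in records:
        for k, v in rec.items():
            if isinstance(v, float):
                rec[k] = round4(v)
    if path.suffix == ".csv":
        pd.DataFrame.from_records(records).to_csv(path, index=False, float_format="%.4f")
    elif path.suffix == ".json":
        path.write_text(json.dumps(records, indent=2))
    else:
        raise ValidationError(f"unsupported report format: {path.suffix}")


def read_report(path: str | Path) -> MetricsReport:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    if path.suffix == ".csv":
        frame = pd.read_csv(path, dtype={"case_id": str})
    elif path.suffix == ".json":
        frame = pd.DataFrame.from_records(json.loads(path.read_text()))
    else:
        raise ValidationError(f"unsupported report format: {path.suffix}")
    rows = []
    mean_row = None
    for rec in frame.to_dict(orient="records"):
        row = MetricsRow(
            case_id=str(rec["case_id"]),
            **{name: float(rec[name]) for name in METRIC_NAMES},
        )
        if row.case_id == "mean":
            mean_row = row
        else:
            rows.append(row)
    if mean_row is None:
        mean_row = aggregate(rows).mean_row
    return MetricsReport(rows=tuple(rows), mean_row=mean_row)
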