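"""Segmentation accuracy metrics: confusion counts and the XOR border error.

The border error (Hance's metric) is

    Area(AutomaticBorder XOR ManualBorder) / Area(ManualBorder)
        = (FP + FN) / (TP + FN),

the pixelwise disagreement between the automatic and the manually drawn
lesion region, normalized by the manual region's area.  It can exceed 1
when the automatic region is badly misplaced.  Precision TP/(TP+FP)
(positive predictive value), recall TP/(TP+FN) (sensitivity) and accuracy
(TP+TN)/total complete the report.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Dict, Iterable, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "UndefinedMetricError",
    "confusion",
    "border_error",
    "precision_recall_accuracy",
    "evaluate_masks",
    "batch_report",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is empty (degenerate ground truth)."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def _check_pair(auto: np.ndarray, manual: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    auto = np.asarray(auto, dtype=bool)
    manual = np.asarray(manual, dtype=bool)
    if auto.shape != manual.shape:
        raise ValueError(f"mask shapes differ: {auto.shape} vs {manual.shape}")
    return auto, manual


def confusion(auto: np.ndarray, manual: np.ndarray) -> ConfusionCounts:
    """Pixel confusion counts of an automatic mask against a manual one."""
    auto, manual = _check_pair(auto, manual)
    tp = int(np.count_nonzero(auto & manual))
    fp = int(np.count_nonzero(auto & ~manual))
    fn = int(np.count_nonzero(~auto & manual))
    tn = auto.size - tp - fp - fn
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def border_error(auto: np.ndarray, manual: np.ndarray) -> float:
    """XOR border error Area(auto XOR manual) / Area(manual).

    Computed both as a pixelwise XOR and from confusion counts
    (FP + FN)/(TP + FN); the two must agree exactly.  An empty manual mask
    is an error: degenerate ground truth should fail loudly, not yield 0/0.
    """
    auto, manual = _check_pair(auto, manual)
    manual_area = int(np.count_nonzero(manual))
    if manual_area == 0:
        raise UndefinedMetricError("manual mask has no positive pixels")
    xor_area = int(np.count_nonzero(auto ^ manual))
    cc = confusion(auto, manual)
    by_counts = (cc.FP + cc.FN) / (cc.TP + cc.FN)
    by_xor = xor_area / manual_area
    assert abs(by_xor - by_counts) < 1e-12, "XOR and confusion-count formulations diverge"
    return by_xor


def precision_recall_accuracy(cc: ConfusionCounts) -> Tuple[float, float, float]:
    """(precision, recall, accuracy) from confusion counts."""
    if cc.TP + cc.FP == 0:
        raise UndefinedMetricError("precision undefined: no predicted positives")
    if cc.TP + cc.FN == 0:
        raise UndefinedMetricError("recall undefined: no actual positives")
    precision = cc.TP / (cc.TP + cc.FP)
    recall = cc.TP / (cc.TP + cc.FN)
    accuracy = (cc.TP + cc.TN) / cc.total
    return precision, recall, accuracy


@dataclass(frozen=True)
class EvalReport:
    """Full per-image evaluation of an automatic border."""

    border_error: float
    precision: float
    recall: float
    accuracy: float
    TP: int
    FP: int
    FN: int
    TN: int

    def to_dict(self) -> Dict[str, float]:
        return asdict(self)


def evaluate_masks(auto: np.ndarray, manual: np.ndarray) -> EvalReport:
    """Evaluate one automatic mask against its ground truth."""
    cc = confusion(auto, manual)
    be = border_error(auto, manual)
    precision, recall, accuracy = precision_recall_accuracy(cc)
    return EvalReport(
        border_error=be,
        precision=precision,
        recall=recall,
        accuracy=accuracy,
        TP=cc.TP,
        FP=cc.FP,
        FN=cc.FN,
        TN=cc.TN,
    )


def batch_report(rows: Iterable[Tuple[str, EvalReport]]) -> pd.DataFrame:
    """One row per image plus min/max/mean/stdev summary rows.

    Columns mirror a per-method results table (border error, precision,
    recall, accuracy), so a user with their own image set can reproduce a
    like-for-like comparison.
    """
    records = [
        {"image": name, **report.to_dict()} for name, report in rows
    ]
    df = pd.DataFrame.from_records(records)
    if df.empty:
        return df
    metric_cols = ["border_error", "precision", "recall", "accuracy"]
    summary = pd.DataFrame(
        {
            "image": ["min", "max", "mean", "stdev"],
            **{
                col: [
                    df[col].min(),
                    df[col].max(),
                    df[col].mean(),
                    df[col].std(ddof=1) if len(df) > 1 else 0.0,
                ]
                for col in metric_cols
            },
        }
    )
    return pd.concat([df, summary], ignore_index=True)
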