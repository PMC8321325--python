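"""Confusion-count segmentation metrics: JA, DC, ACC, SEN, SPE.

With TP/TN/FP/FN counted at a binarization threshold (default 0.5)::

    JA  = TP / (TP + FP + FN)          Jaccard index (primary metric)
    DC  = 2 TP / (2 TP + FP + FN)      Dice coefficient  (= 2 JA / (1 + JA))
    ACC = (TP + TN) / total
    SEN = TP / (TP + FN)               sensitivity / recall on lesion pixels
    SPE = TN / (TN + FP)               specificity on skin pixels

Dataset-level numbers are means of per-image metrics.  Degenerate
denominators (e.g. SEN on an image without foreground) score 1 when the
condition is vacuously satisfied (nothing to find and nothing predicted) and
0 otherwise, and the affected rows are flagged in the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

METRIC_NAMES = ("JA", "DC", "ACC", "SEN", "SPE")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    threshold: float = 0.5

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred: np.ndarray, truth: np.ndarray, threshold: float = 0.5) -> ConfusionCounts:
    """Counts from ``pred >= threshold`` against a binary truth mask."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred >= threshold
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        threshold=threshold,
    )


def _ratio(num: int, den: int, vacuous_ok: bool) -> float:
    if den == 0:
        return 1.0 if vacuous_ok else 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> dict:
    """The five metrics; flags degenerate denominators under ``"degenerate"``."""
    degenerate = (c.tp + c.fp + c.fn == 0) or (c.tp + c.fn == 0) or (c.tn + c.fp == 0)
    return {
        "JA": _ratio(c.tp, c.tp + c.fp + c.fn, vacuous_ok=True),
        "DC": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, vacuous_ok=True),
        "ACC": (c.tp + c.tn) / c.total,
        "SEN": _ratio(c.tp, c.tp + c.fn, vacuous_ok=(c.fp == 0)),
        "SPE": _ratio(c.tn, c.tn + c.fp, vacuous_ok=(c.fn == 0)),
        "degenerate": degenerate,
    }


def jaccard(pred: np.ndarray, truth: np.ndarray, threshold: float = 0.5) -> float:
    return metrics_from_counts(confusion(pred, truth, threshold))["JA"]


def report_frame(rows: list[dict]) -> pd.DataFrame:
    """Per-image metric rows plus a summary row of means (image_id='mean')."""
    df = pd.DataFrame(rows, columns=["image_id", "TP", "TN", "FP", "FN",
                                     *METRIC_NAMES, "degenerate"])
    summary = {"image_id": "mean", "degenerate": bool(df["degenerate"].any())}
    for col in ("TP", "TN", "FP", "FN", *METRIC_NAMES):
        summary[col] = df[col].mean()
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)


def evaluate_predictions(preds, truths, ids=None, threshold: float = 0.5) -> pd.DataFrame:
    """Metric table for parallel lists of probability maps and truth masks."""
    rows = []
    for i, (p, t) in enumerate(zip(preds, truths)):
        c = confusion(p, t, threshold)
        m = metrics_from_counts(c)
        rows.append({"image_id": ids[i] if ids is not None else i,
                     "TP": c.tp, "TN": c.tn, "FP": c.fp, "FN": c.fn, **m})
    return report_frame(rows)


def mean_metric(df: pd.DataFrame, name: str = "JA") -> float:
    """The dataset-level mean of a metric from a report frame."""
    return float(df.loc[df["image_id"] == "mean", name].iloc[0])
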