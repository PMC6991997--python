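"""Pixel-wise evaluation of predicted optic-disc masks.

Standard confusion-matrix metrics over the (full) image: sensitivity
SN = TP/(TP+FN), specificity SP = TN/(TN+FP), accuracy
Acc = (TP+TN)/total, and the area-overlap (Jaccard) AOL = TP/(TP+FP+FN).
Localization is scored by whether the predicted disc center falls inside
the ground-truth disc mask (boundary inclusive).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InputError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class SegMetrics:
    """SN/SP/Acc/AOL; a metric with a zero denominator is None (undefined)."""

    sn: float | None
    sp: float | None
    acc: float | None
    aol: float | None


def confusion(
    pred: np.ndarray, truth: np.ndarray, eval_region: np.ndarray | None = None
) -> ConfusionCounts:
    """Count TP/FP/TN/FN over ``eval_region`` (full image by default)."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise InputError("prediction and truth shapes do not match")
    if eval_region is None:
        p, t = pred.ravel(), truth.ravel()
    else:
        if eval_region.shape != pred.shape:
            raise InputError("eval_region shape does not match")
        if not eval_region.any():
            raise InputError("empty evaluation region")
        p, t = pred[eval_region], truth[eval_region]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(p.size - tp - fp - fn)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def seg_metrics(c: ConfusionCounts) -> SegMetrics:
    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return SegMetrics(
        sn=ratio(c.tp, c.tp + c.fn),
        sp=ratio(c.tn, c.tn + c.fp),
        acc=ratio(c.tp + c.tn, c.total),
        aol=ratio(c.tp, c.tp + c.fp + c.fn),
    )


def localization_hit(pred_center: tuple[float, float], truth_mask: np.ndarray) -> bool:
    """True iff the predicted center's pixel lies inside the truth mask."""
    r = int(round(pred_center[0]))
    c = int(round(pred_center[1]))
    h, w = truth_mask.shape
    if not (0 <= r < h and 0 <= c < w):
        return False
    return bool(truth_mask[r, c])


def evaluate_pairs(
    pairs: list[tuple[str, np.ndarray, np.ndarray]],
) -> list[dict]:
    """Score (name, pred, truth) mask pairs; appends a mean row."""
    rows = []
    for name, pred, truth in pairs:
        m = seg_metrics(confusion(pred, truth))
        rows.append({"name": name, "sn": m.sn, "sp": m.sp, "acc": m.acc, "aol": m.aol})
    if rows:
        mean_row = {"name": "mean"}
        for k in ("sn", "sp", "acc", "aol"):
            vals = [r[k] for r in rows if r[k] is not None]
            mean_row[k] = float(np.mean(vals)) if vals else None
        rows.append(mean_row)
    return rows


def write_report(rows: list[dict], out_path: str | Path) -> None:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with out_path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["name", "sn", "sp", "acc", "aol"])
        writer.writeheader()
        writer.writerows(rows)
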