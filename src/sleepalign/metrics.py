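"""Evaluation metrics: accuracy, per-class precision/recall/F1, macro-F1.

One-vs-rest counts are computed per stage; accuracy is the fraction of
correctly staged epochs (sum of per-class true positives over N), and the
macro-F1 is the unweighted mean of the five per-class F1 scores — the
average always divides by the full class count T=5, so a stage absent from
an evaluation set still contributes a zero term.  Classes with undefined
precision or recall receive F1 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_edf import StageLabel

N_CLASSES = 5


@dataclass
class ConfusionCounts:
    """One-vs-rest counts per class; invariant TP+FP+TN+FN == N for each."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    n: int

    def __post_init__(self):
        for arr in (self.tp, self.fp, self.tn, self.fn):
            if arr.shape != (N_CLASSES,):
                raise ValueError("per-class count arrays must have length 5")
        totals = self.tp + self.fp + self.tn + self.fn
        if not np.all(totals == self.n):
            raise ValueError("inconsistent confusion counts")


def confusion(y_true, y_pred) -> ConfusionCounts:
    t = np.asarray([int(v) for v in y_true])
    p = np.asarray([int(v) for v in y_pred])
    if t.size == 0:
        raise ValueError("empty label vectors")
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if np.any((t < 0) | (t >= N_CLASSES)) or np.any((p < 0) | (p >= N_CLASSES)):
        raise ValueError("labels must be stage codes 0..4")
    table = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(table, (t, p), 1)
    tp = np.diag(table).astype(int)
    fp = table.sum(axis=0) - tp
    fn = table.sum(axis=1) - tp
    n = int(t.size)
    tn = n - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, n=n)


def accuracy(c: ConfusionCounts) -> float:
    """Sum of per-class true positives over the total sample count."""
    if c.n == 0:
        raise ValueError("accuracy undefined for N = 0")
    return float(c.tp.sum() / c.n)


def precision_recall(c: ConfusionCounts) -> tuple[np.ndarray, np.ndarray]:
    """Per-class precision and recall with the zero-division-to-zero rule."""
    with np.errstate(invalid="ignore", divide="ignore"):
        pre = np.where(c.tp + c.fp > 0, c.tp / np.maximum(c.tp + c.fp, 1), 0.0)
        rec = np.where(c.tp + c.fn > 0, c.tp / np.maximum(c.tp + c.fn, 1), 0.0)
    return pre, rec


def macro_f1(c: ConfusionCounts) -> tuple[float, np.ndarray]:
    """Unweighted mean F1 over all five classes; returns (macro, per-class)."""
    if c.n == 0:
        raise ValueError("F1 undefined for N = 0")
    pre, rec = precision_recall(c)
    denom = pre + rec
    f1 = np.where(denom > 0, 2 * pre * rec / np.where(denom > 0, denom, 1), 0.0)
    return float(f1.mean()), f1


def balanced_accuracy(c: ConfusionCounts) -> float:
    """Mean per-class recall over the classes present in the reference."""
    _, rec = precision_recall(c)
    present = (c.tp + c.fn) > 0
    if not present.any():
        raise ValueError("no class present in the reference labels")
    return float(rec[present].mean())


def metrics_report(y_true, y_pred) -> pd.DataFrame:
    """Overall and per-stage metrics as a table (stages in W..REM order)."""
    c = confusion(y_true, y_pred)
    pre, rec = precision_recall(c)
    macro, f1 = macro_f1(c)
    rows = [{"stage": "overall", "precision": np.nan, "recall": np.nan,
             "f1": macro, "accuracy": accuracy(c),
             "balanced_accuracy": balanced_accuracy(c)}]
    for s in StageLabel:
        rows.append({"stage": s.name, "precision": pre[s], "recall": rec[s],
                     "f1": f1[s], "accuracy": np.nan, "balanced_accuracy": np.nan})
    return pd.DataFrame(rows)
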