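"""Organization-Index threshold calibration by F1 sweep.

Given electrogram segments labeled by whether their DF peak is
significant, the OI significance threshold is chosen by sweeping a 0-1
grid at 0.05 spacing and scoring each threshold with

    Pre = TP / (TP + FP),  recall = TP / (TP + FN),
    F1 = 2 * Pre * recall / (Pre + recall)

where a segment is predicted positive when its OI is at or above the
threshold. Degenerate 0/0 ratios are defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SweepResult:
    """Per-threshold confusion counts and scores, plus the F1 argmax."""

    table: pd.DataFrame           # threshold, tp, fp, fn, precision, recall, f1
    best_threshold: float
    best_f1: float


def confusion_at(
    oi_values: np.ndarray, labels: np.ndarray, threshold: float
) -> tuple[int, int, int]:
    """(TP, FP, FN) with OI >= threshold counted as predicted positive."""
    oi = np.asarray(oi_values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if oi.size == 0:
        raise ValueError("no segments given")
    if oi.shape != y.shape:
        raise ValueError("oi_values and labels must align")
    if np.any((oi < 0) | (oi > 1)):
        raise ValueError("OI values must lie in [0, 1]")
    pred = oi >= threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    return tp, fp, fn


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    pre = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    return pre, rec, f1


def sweep_f1(
    oi_values: np.ndarray, labels: np.ndarray, step: float = 0.05
) -> SweepResult:
    """Score every threshold on the inclusive 0..1 grid at ``step``.

    Requires both classes to be present (F1 is degenerate otherwise).
    The argmax resolves ties toward the lowest threshold.
    """
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError(
            "both positive and negative segments are required: with a "
            "single class the F1 score cannot rank thresholds"
        )
    n_steps = int(round(1.0 / step))
    thresholds = np.round(np.arange(n_steps + 1) * step, 10)
    rows = []
    for thr in thresholds:
        tp, fp, fn = confusion_at(oi_values, y, thr)
        pre, rec, f1 = precision_recall_f1(tp, fp, fn)
        rows.append((thr, tp, fp, fn, pre, rec, f1))
    table = pd.DataFrame(
        rows, columns=["threshold", "tp", "fp", "fn", "precision", "recall", "f1"]
    )
    best = int(np.argmax(table["f1"].to_numpy()))   # first max = lowest threshold
    return SweepResult(table, float(table.loc[best, "threshold"]),
                       float(table.loc[best, "f1"]))
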