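"""Confusion-matrix construction and per-class classification metrics.

Reports follow the layout common in the histopathology-classification
literature: one row per class with one-vs-rest accuracy, precision,
recall, F1 and AUC (all in percent), closed by an unweighted macro-average
row. Per-class "accuracy" is the one-vs-rest accuracy
``(TP + TN) / total``, which is why each class's value sits near 100 even
when the overall micro-accuracy is lower.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "confusion_matrix",
    "per_class_metrics",
    "auc_ovr",
    "macro_average",
    "EvaluationReport",
    "build_report",
    "micro_accuracy",
]

REPORT_COLUMNS = ("Class", "Accuy", "Precn", "Recal", "Fscore", "AUCscore")


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size and (min(y_true.min(), y_pred.min()) < 0
                        or max(y_true.max(), y_pred.max()) >= n_classes):
        raise ValueError("labels must lie in [0, n_classes)")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def micro_accuracy(cm: np.ndarray) -> float:
    """Overall accuracy in percent: trace / total."""
    total = cm.sum()
    return float(100.0 * np.trace(cm) / total) if total else 0.0


def per_class_metrics(cm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-rest accuracy/precision/recall/F1 per class, in percent.

    Returns ``(metrics, undefined)`` where ``metrics`` is (n, 4) with
    columns accuracy, precision, recall, F1 and ``undefined`` is a boolean
    (n, 4) flag marking 0/0 ratios that were reported as 0.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.shape[0] < 2:
        raise ValueError("confusion matrix must be square with n >= 2")
    n = cm.shape[0]
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    out = np.zeros((n, 4))
    undefined = np.zeros((n, 4), dtype=bool)
    for c in range(n):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        tn = total - tp - fp - fn
        out[c, 0] = 100.0 * (tp + tn) / total
        prec, undefined[c, 1] = _ratio(tp, tp + fp)
        rec, undefined[c, 2] = _ratio(tp, tp + fn)
        out[c, 1] = 100.0 * prec
        out[c, 2] = 100.0 * rec
        if prec + rec > 0:
            out[c, 3] = 100.0 * 2 * prec * rec / (prec + rec)
        else:
            undefined[c, 3] = undefined[c, 1] and undefined[c, 2]
    return out, undefined


def _ratio(num, den) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def auc_ovr(y_true, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-rest AUC per class (percent) via the rank statistic.

    For class ``c`` the AUC is the Mann-Whitney probability that a random
    class-``c`` sample receives a higher class-``c`` score than a random
    rest sample, with ties counted half. Classes absent from ``y_true``
    (either side empty) are flagged undefined and reported as 0.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or len(y_true) != len(scores):
        raise ValueError("scores must be (n_samples, n_classes) matching y_true")
    n_classes = scores.shape[1]
    auc = np.zeros(n_classes)
    undefined = np.zeros(n_classes, dtype=bool)
    for c in range(n_classes):
        pos = y_true == c
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            undefined[c] = True
            continue
        ranks = _midranks(scores[:, c])
        u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
        auc[c] = 100.0 * u / (n_pos * n_neg)
    return auc, undefined


def _midranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties replaced by their average rank."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def macro_average(rows: np.ndarray, auc: np.ndarray, auc_undefined: np.ndarray) -> np.ndarray:
    """Unweighted mean row; AUC averages only over classes where defined."""
    rows = np.asarray(rows)
    if rows.size == 0:
        raise ValueError("need at least one class row")
    mean4 = rows.mean(axis=0)
    valid = ~np.asarray(auc_undefined, dtype=bool)
    mean_auc = float(np.mean(auc[valid])) if valid.any() else float("nan")
    return np.append(mean4, mean_auc)


@dataclass
class EvaluationReport:
    """Per-class metric table plus macro average for one named split."""

    class_names: list[str]
    metrics: np.ndarray        # (n, 5): accuracy, precision, recall, F1, AUC
    average: np.ndarray        # (5,)
    confusion: np.ndarray      # (n, n)
    split: str = ""
    auc_undefined: np.ndarray | None = None

    def to_rows(self) -> list[list]:
        rows = [[name, *np.round(row, 2)] for name, row in zip(self.class_names, self.metrics)]
        rows.append(["Average", *np.round(self.average, 2)])
        return rows

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(REPORT_COLUMNS)
            writer.writerows(self.to_rows())

    def to_dict(self) -> dict:
        return {
            "split": self.split,
            "columns": list(REPORT_COLUMNS[1:]),
            "classes": {
                name: [float(v) for v in row]
                for name, row in zip(self.class_names, self.metrics)
            },
            "average": [float(v) for v in self.average],
            "micro_accuracy": micro_accuracy(self.confusion),
        }


def build_report(
    y_true, y_pred, scores: np.ndarray, class_names: list[str], split: str = ""
) -> EvaluationReport:
    """Assemble the full per-class report for one evaluated split."""
    n = len(class_names)
    cm = confusion_matrix(y_true, y_pred, n)
    base, _flags = per_class_metrics(cm)
    auc, auc_undef = auc_ovr(y_true, scores)
    metrics = np.column_stack([base, auc])
    average = macro_average(base, auc, auc_undef)
    return EvaluationReport(list(class_names), metrics, average, cm, split, auc_undef)
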