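"""Confusion-matrix accuracy metrics: OA, AA, Cohen's kappa, per-class rates.

OA is the trace over the total, in percent. AA comes in two modes:
``mean_recall`` (the default) averages the per-class recalls
diagonal/row-sum; ``literal_ovr`` averages per-class one-vs-rest binary
accuracies (TP+TN)/(TP+TN+FP+FN), which counts true negatives and therefore
sits well above OA for multi-class problems. Kappa is
(P_l − P_x)/(1 − P_x) with P_l the observed agreement and P_x the chance
agreement Σ_c row_c·col_c / total².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "cross_entropy",
           "overall_accuracy", "average_accuracy", "kappa", "evaluate"]


def cross_entropy(p: np.ndarray, labels: np.ndarray, eps: float = 1e-12,
                  tol: float = 1e-6) -> float:
    """Mean negative log-probability at the true class; labels are 1..M."""
    p = np.asarray(p, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if p.ndim != 2 or p.shape[0] != labels.shape[0]:
        raise ValueError("p must be (N, M) matching labels")
    row_sums = p.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > tol):
        raise ValueError("probability rows must sum to 1")
    m = p.shape[1]
    if labels.min() < 1 or labels.max() > m:
        raise ValueError(f"labels must be in 1..{m}")
    picked = p[np.arange(p.shape[0]), labels - 1]
    return float(-np.mean(np.log(np.clip(picked, eps, None))))


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def m(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(y_true, y_pred, m: int,
              class_names: dict[int, str] | None = None) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 1 or arr.max() > m):
            raise ValueError(f"{name} labels must be in 1..{m}")
    counts = np.zeros((m, m), dtype=np.int64)
    np.add.at(counts, (y_true - 1, y_pred - 1), 1)
    return ConfusionMatrix(counts, class_names or {})


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """100 · trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def per_class_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    """Per-class recall in percent; NaN for classes with no true samples."""
    row = cm.counts.sum(axis=1).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        return 100.0 * np.diag(cm.counts) / row


def average_accuracy(cm: ConfusionMatrix, mode: str = "mean_recall") -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if mode == "mean_recall":
        rows = cm.counts.sum(axis=1)
        empty = np.flatnonzero(rows == 0)
        if empty.size:
            raise ValueError(
                f"class(es) {[int(c) + 1 for c in empty]} have no true samples")
        return float(np.mean(100.0 * np.diag(cm.counts) / rows))
    if mode == "literal_ovr":
        n = cm.total
        accs = []
        for c in range(cm.m):
            tp = cm.counts[c, c]
            fn = cm.counts[c].sum() - tp
            fp = cm.counts[:, c].sum() - tp
            tn = n - tp - fn - fp
            accs.append(100.0 * (tp + tn) / n)
        return float(np.mean(accs))
    raise ValueError(f"unknown AA mode: {mode}")


def kappa(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    n = float(cm.total)
    p_l = np.trace(cm.counts) / n
    p_x = float(cm.counts.sum(axis=1) @ cm.counts.sum(axis=0)) / n ** 2
    if p_x == 1.0:
        raise ValueError("chance agreement is 1; kappa undefined")
    return float((p_l - p_x) / (1.0 - p_x))


@dataclass
class MetricsReport:
    """OA/AA/kappa plus per-class accuracies, serialisable to CSV and JSON."""

    oa: float
    aa: float
    aa_mode: str
    kappa: float
    per_class: dict[str, float]
    confusion: ConfusionMatrix

    def to_frame(self) -> pd.DataFrame:
        rows = [{"class": k, "accuracy_pct": v} for k, v in self.per_class.items()]
        rows += [{"class": "OA (%)", "accuracy_pct": self.oa},
                 {"class": f"AA (%) [{self.aa_mode}]", "accuracy_pct": self.aa},
                 {"class": "Kappa", "accuracy_pct": self.kappa}]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {"OA": self.oa, "AA": self.aa, "aa_mode": self.aa_mode,
                   "Kappa": self.kappa, "per_class": self.per_class,
                   "confusion": self.confusion.counts.tolist()}
        path.write_text(json.dumps(payload, indent=2))
        return path


def report_from_confusion(cm: ConfusionMatrix,
                          aa_mode: str = "mean_recall") -> MetricsReport:
    pc = per_class_accuracy(cm)
    names = {i + 1: cm.class_names.get(i + 1, f"class_{i + 1}")
             for i in range(cm.m)}
    return MetricsReport(
        oa=overall_accuracy(cm),
        aa=average_accuracy(cm, aa_mode),
        aa_mode=aa_mode,
        kappa=kappa(cm),
        per_class={names[i + 1]: float(pc[i]) for i in range(cm.m)},
        confusion=cm,
    )


def evaluate(model, test_set, aa_mode: str = "mean_recall") -> MetricsReport:
    """Run the classifier on a sample set and compute all metrics."""
    if test_set.n_samples == 0:
        raise ValueError("test set is empty")
    y_pred = model.predict(test_set.as_batch())
    m = model.config.n_classes
    cm = confusion(test_set.labels, y_pred, m, dict(test_set.class_names))
    return report_from_confusion(cm, aa_mode)
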