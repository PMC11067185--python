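"""Model evaluation: confusion matrix, per-class one-vs-rest metrics
(precision, recall/sensitivity, F1, specificity, accuracy), overall accuracy,
one-vs-rest ROC curves with trapezoidal AUC, and cohort summary tables.

Per-class metrics reduce the 6-class problem one-vs-rest: for class k,
TP = M[k][k], FP = column-k total minus TP, FN = row-k total minus TP and
TN the rest. When a denominator vanishes (class absent from both truth and
prediction) precision, recall and F1 are reported as 0 — the convention the
performance tables use for an empty class — while specificity degenerates
to 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .data_io import Dataset
from .schema import N_CLASSES, SURVIVAL_CLASS


class UndefinedAUCError(ValueError):
    """One-vs-rest truth contains a single class; the ROC is undefined."""


def confusion(y_true, y_pred, n_classes: int = N_CLASSES) -> np.ndarray:
    """Count matrix with rows = truth, columns = prediction."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} labels out of range 0..{n_classes - 1}")
    M = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(M, (y_true, y_pred), 1)
    return M


def _safe_div(num: float, den: float, default: float = 0.0) -> float:
    return num / den if den > 0 else default


def per_class_metrics(M: np.ndarray, k: int) -> dict[str, float]:
    """One-vs-rest precision, recall, F1, specificity and binary accuracy."""
    M = np.asarray(M)
    n = M.sum()
    tp = M[k, k]
    fp = M[:, k].sum() - tp
    fn = M[k, :].sum() - tp
    tn = n - tp - fp - fn
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    specificity = _safe_div(tn, tn + fp, default=1.0)
    accuracy = _safe_div(tp + tn, n)
    return {"precision": precision, "recall": recall, "f1": f1,
            "specificity": specificity, "accuracy": accuracy}


def roc_and_auc(y_true, scores_k, k: int) -> tuple[list[tuple[float, float]], float]:
    """One-vs-rest ROC for class k by threshold sweep, and trapezoidal AUC.

    Returns the (FPR, TPR) staircase from (0, 0) to (1, 1); ties in score are
    grouped, so the AUC equals the Mann–Whitney pair statistic with ties
    counted one half.
    """
    y_bin = (np.asarray(y_true, dtype=int) == k).astype(int)
    scores_k = np.asarray(scores_k, dtype=float)
    if not np.isfinite(scores_k).all():
        raise ValueError("scores must be finite")
    if y_bin.min() == y_bin.max():
        raise UndefinedAUCError(f"class {k}: only one class present in truth")
    fpr, tpr, _ = _sk_roc_curve(y_bin, scores_k, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_trapezoid_auc(fpr, tpr))


@dataclass
class EvalReport:
    """Per-class and overall performance of one model on one test set."""

    confusion_matrix: np.ndarray
    per_class: list[dict[str, float]]
    auc: list[float | None]
    roc_points: list[list[tuple[float, float]] | None]
    overall_accuracy: float
    model: str = ""

    COLUMNS = ("Precision", "Recall (Sensitivity)", "F1-score", "Accuracy",
               "Specificity", "AUC of ROC curve")

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "overall_accuracy": self.overall_accuracy,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "per_class": [
                {**m, "auc": self.auc[k]} for k, m in enumerate(self.per_class)
            ],
            "roc_points": [
                [[float(a), float(b)] for a, b in pts] if pts is not None else None
                for pts in self.roc_points
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    def _rows(self) -> list[list[str]]:
        rows = []
        for k, m in enumerate(self.per_class):
            auc_str = f"{self.auc[k]:.2f}" if self.auc[k] is not None else "NA"
            rows.append([f"Class {k}", f"{m['precision']:.2f}", f"{m['recall']:.2f}",
                         f"{m['f1']:.2f}", f"{m['accuracy']:.2f}",
                         f"{m['specificity']:.2f}", auc_str])
        return rows

    def to_markdown(self) -> str:
        header = ["Class", *self.COLUMNS]
        lines = ["| " + " | ".join(header) + " |",
                 "|" + "|".join(["---"] * len(header)) + "|"]
        lines += ["| " + " | ".join(r) + " |" for r in self._rows()]
        lines.append(f"\nOverall accuracy = {self.overall_accuracy:.2f}")
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> None:
        header = ["Class", *self.COLUMNS]
        lines = [",".join(header)]
        lines += [",".join(f'"{c}"' if "," in c else c for c in r) for r in self._rows()]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def evaluate(y_true, y_pred, scores=None, n_classes: int = N_CLASSES,
             model: str = "") -> EvalReport:
    """Assemble the full report; AUC entries are None where undefined or
    where no scores are given."""
    M = confusion(y_true, y_pred, n_classes)
    per_class = [per_class_metrics(M, k) for k in range(n_classes)]
    aucs: list[float | None] = [None] * n_classes
    rocs: list[list[tuple[float, float]] | None] = [None] * n_classes
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (len(np.asarray(y_true)), n_classes):
            raise ValueError(f"scores must be (n, {n_classes}), got {scores.shape}")
        for k in range(n_classes):
            try:
                rocs[k], aucs[k] = roc_and_auc(y_true, scores[:, k], k)
            except UndefinedAUCError:
                pass
    n = M.sum()
    overall = float(np.trace(M) / n) if n else 0.0
    return EvalReport(confusion_matrix=M, per_class=per_class, auc=aucs,
                      roc_points=rocs, overall_accuracy=overall, model=model)


# ---------------------------------------------------------------------------
# cohort summary (counts and half-up one-decimal percentages)

def _pct(count: int, n: int) -> float:
    return float(
        (Decimal(100 * count) / Decimal(n)).quantize(Decimal("0.1"), ROUND_HALF_UP)
    )


@dataclass
class CohortSummary:
    """Per-variable level counts with percentages of the cohort size."""

    n: int
    tables: dict[str, list[tuple[str, int, float]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "variables": {
                var: [{"level": lev, "count": c, "percent": p} for lev, c, p in rows]
                for var, rows in self.tables.items()
            },
        }

    def to_csv(self, path: str | Path) -> None:
        lines = ["variable,level,count,percent"]
        for var, rows in self.tables.items():
            lines += [f"{var},{lev},{c},{p}" for lev, c, p in rows]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    def lookup(self, variable: str, level: str) -> tuple[int, float]:
        for lev, c, p in self.tables[variable]:
            if lev == level:
                return c, p
        raise KeyError((variable, level))


def summarize_cohort(ds: Dataset) -> CohortSummary:
    """Level counts and one-decimal percentages per variable, survival
    classes included."""
    n = len(ds)
    if n == 0:
        raise ValueError("cannot summarize an empty dataset")
    out = CohortSummary(n=n)
    for var in ds.schema.variables:
        col = ds.df[var.name]
        out.tables[var.name] = [
            (lev, int((col == lev).sum()), _pct(int((col == lev).sum()), n))
            for lev in var.levels
        ]
    cls = ds.df[SURVIVAL_CLASS]
    if cls.notna().any():
        out.tables[SURVIVAL_CLASS] = [
            (str(k), int((cls == k).sum()), _pct(int((cls == k).sum()), n))
            for k in range(N_CLASSES)
        ]
    return out
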