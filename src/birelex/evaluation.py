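"""Confusion matrices, per-class precision/recall/F1 and report rendering.

Conventions: the summary precision/recall/F1 are macro averages (the
unweighted mean over classes), and every 0/0 ratio evaluates to 0 so that
degenerate folds aggregate cleanly.  Reports display at 3 decimals; the
stored values keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .corpus import DEFAULT_SCHEMA, LabelSchema

__all__ = [
    "ClassMetrics",
    "EvalReport",
    "confusion_matrix",
    "per_class_prf",
    "f1_score",
    "aggregate_report",
    "evaluate",
]


def _safe_div(num: float, den: float) -> float:
    return float(num) / float(den) if den else 0.0


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when P + R = 0."""
    return _safe_div(2.0 * precision * recall, precision + recall)


def confusion_matrix(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    schema: LabelSchema = DEFAULT_SCHEMA,
) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class.

    Class order follows ``schema.relation_labels``.
    """
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    n = len(schema.relation_labels)
    mat = np.zeros((n, n), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        mat[schema.label_index(t), schema.label_index(p)] += 1
    return mat


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


def per_class_prf(confusion: np.ndarray) -> list[ClassMetrics]:
    """Per-class precision, recall, F1 and support from a confusion matrix.

    For class c: TP is the diagonal entry, FP the rest of the column, FN the
    rest of the row; P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R).
    """
    confusion = np.asarray(confusion)
    tp = np.diag(confusion).astype(float)
    support = confusion.sum(axis=1)
    predicted = confusion.sum(axis=0)
    out = []
    for c in range(confusion.shape[0]):
        p = _safe_div(tp[c], predicted[c])
        r = _safe_div(tp[c], support[c])
        out.append(ClassMetrics(p, r, f1_score(p, r), int(support[c])))
    return out


@dataclass
class EvalReport:
    """Full evaluation of one prediction run."""

    labels: tuple[str, ...]
    confusion: np.ndarray
    per_class: Mapping[str, ClassMetrics]
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def metric(self, name: str) -> float:
        try:
            return float(getattr(self, name))
        except AttributeError:
            raise KeyError(f"unknown metric: {name!r}") from None

    @property
    def n_instances(self) -> int:
        return int(self.confusion.sum())

    def render_text(self) -> str:
        """Per-class report: one row per class plus the macro summary."""
        width = max(len(l) for l in self.labels)
        lines = [
            f"{'Class':<{width}}  Precision  Recall  F1-score  Support"
        ]
        for label in self.labels:
            m = self.per_class[label]
            lines.append(
                f"{label:<{width}}  {m.precision:9.3f}  {m.recall:6.3f}  "
                f"{m.f1:8.3f}  {m.support:7d}"
            )
        lines.append(
            f"{'macro':<{width}}  {self.macro_precision:9.3f}  "
            f"{self.macro_recall:6.3f}  {self.macro_f1:8.3f}  "
            f"{self.n_instances:7d}"
        )
        lines.append(f"accuracy: {self.accuracy:.3f}")
        return "\n".join(lines)

    def to_tsv(self) -> str:
        rows = ["class\tprecision\trecall\tf1\tsupport"]
        for label in self.labels:
            m = self.per_class[label]
            rows.append(
                f"{label}\t{m.precision:.3f}\t{m.recall:.3f}"
                f"\t{m.f1:.3f}\t{m.support}"
            )
        rows.append(
            f"macro\t{self.macro_precision:.3f}\t{self.macro_recall:.3f}"
            f"\t{self.macro_f1:.3f}\t{self.n_instances}"
        )
        rows.append(f"accuracy\t{self.accuracy:.3f}\t\t\t")
        return "\n".join(rows) + "\n"


def aggregate_report(
    confusion: np.ndarray, schema: LabelSchema = DEFAULT_SCHEMA
) -> EvalReport:
    """Build an :class:`EvalReport` from a confusion matrix.

    Accuracy is trace/total; macro metrics are unweighted class means.
    """
    confusion = np.asarray(confusion, dtype=np.int64)
    metrics = per_class_prf(confusion)
    total = confusion.sum()
    return EvalReport(
        labels=tuple(schema.relation_labels),
        confusion=confusion,
        per_class=dict(zip(schema.relation_labels, metrics)),
        accuracy=_safe_div(np.trace(confusion), total),
        macro_precision=float(np.mean([m.precision for m in metrics])),
        macro_recall=float(np.mean([m.recall for m in metrics])),
        macro_f1=float(np.mean([m.f1 for m in metrics])),
    )


def evaluate(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    schema: LabelSchema = DEFAULT_SCHEMA,
) -> EvalReport:
    """Convenience: confusion + aggregate report from label vectors."""
    return aggregate_report(confusion_matrix(y_true, y_pred, schema), schema)
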