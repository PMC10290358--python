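"""Confusion-matrix evaluation of tile predictions (positive class = reed)."""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

from .dataset import LABELS

__all__ = ["ConfusionMatrix", "confusion_counts", "summary_metrics"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of true/false positives and negatives for the reed class."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def as_table(self) -> str:
        """The 2x2 matrix as an aligned text table (rows = true class)."""
        rows = [
            ["", "pred reed", "pred non_reed"],
            ["true reed", str(self.TP), str(self.FN)],
            ["true non_reed", str(self.FP), str(self.TN)],
        ]
        widths = [max(len(r[i]) for r in rows) for i in range(3)]
        return "\n".join(
            "  ".join(cell.rjust(w) for cell, w in zip(row, widths)) for row in rows
        )


def confusion_counts(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    positive: str = "reed",
) -> ConfusionMatrix:
    """Tally the four confusion groups over paired label sequences."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"label sequences differ in length: {len(true_labels)} vs {len(predicted_labels)}"
        )
    if positive not in LABELS:
        raise ValueError(f"unknown positive class {positive!r}")
    tp = fp = tn = fn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t not in LABELS or p not in LABELS:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r}); expected one of {LABELS}")
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(TP=tp, FP=fp, TN=tn, FN=fn)


def summary_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Accuracy, precision, recall, specificity and F1 from the counts.

    Ratios with a zero denominator are reported as ``None`` (missing)
    rather than coerced to 0, so degenerate splits cannot silently
    inflate a metric.
    """
    if cm.n == 0:
        raise ValueError("cannot summarise an empty confusion matrix")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    precision = ratio(cm.TP, cm.TP + cm.FP)
    recall = ratio(cm.TP, cm.TP + cm.FN)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": (cm.TP + cm.TN) / cm.n,
        "precision": precision,
        "recall": recall,
        "specificity": ratio(cm.TN, cm.TN + cm.FP),
        "f1": f1,
    }


def write_metrics_json(cm: ConfusionMatrix, path) -> None:
    """metrics.json: the four counts plus the derived metrics."""
    payload = {"TP": cm.TP, "FP": cm.FP, "TN": cm.TN, "FN": cm.FN}
    payload.update(summary_metrics(cm))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
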