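"""One-vs-rest evaluation for the 5-class modification task.

Each class is scored against all other classes pooled as negatives:
recall = TP/(TP+FN), precision = TP/(TP+FP),
accuracy = (TP+TN)/(TP+TN+FP+FN), F1 = 2PR/(P+R), and

    MCC = (TP·TN − FP·FN) / √((TN+FN)(TP+FP)(TN+FP)(TP+FN))

plus the areas under the ROC curve (trapezoidal) and the
precision-recall curve (precision-step interpolation) computed from
the per-class probability scores.  Degenerate 0/0 ratios are defined
as 0 and warned about, which keeps small synthetic folds usable.
Overall accuracy is the fraction of correctly classified instances
over all classes jointly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from math import sqrt
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .records import LABELS

METRIC_COLUMNS = ("accuracy", "precision", "recall", "f1", "mcc", "roc_auc", "pr_auc")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"degenerate denominator in {name}; returning 0", stacklevel=3)
        return 0.0
    return num / den


def confusion_counts(
    predicted: Sequence, true: Sequence, positive_class
) -> ConfusionCounts:
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("predicted and true label vectors differ in length")
    pred_pos = predicted == positive_class
    true_pos = true == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pred_pos & true_pos)),
        fp=int(np.sum(pred_pos & ~true_pos)),
        tn=int(np.sum(~pred_pos & ~true_pos)),
        fn=int(np.sum(~pred_pos & true_pos)),
    )


def class_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Confusion-derived metrics with the 0/0 → 0 convention."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics for zero evaluated instances")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    recall = _ratio(tp, tp + fn, "recall")
    precision = _ratio(tp, tp + fp, "precision")
    accuracy = (tp + tn) / counts.total
    f1 = _ratio(2 * precision * recall, precision + recall, "F1")
    mcc_den = sqrt((tn + fn) * (tp + fp) * (tn + fp) * (tp + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "MCC")
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "mcc": mcc,
    }


def overall_accuracy(predicted: Sequence, true: Sequence) -> float:
    """Correctly classified instances / total instances."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("predicted and true label vectors differ in length")
    if predicted.size == 0:
        raise ValueError("overall accuracy is undefined for empty inputs")
    return float((predicted == true).mean())


def ranked_areas(
    scores: Sequence[float], true: Sequence, positive_class
) -> tuple[float, float]:
    """(ROC area, PR area) for one class's probability scores.

    ROC area is trapezoidal (ties contribute half); PR area uses the
    step-wise precision interpolation.
    """
    scores = np.asarray(scores, dtype=float)
    true = np.asarray(true)
    binary = (true == positive_class).astype(int)
    if binary.sum() == 0:
        raise ValueError(f"class {positive_class!r} absent from the true labels")
    if binary.sum() == len(binary):
        raise ValueError(f"class {positive_class!r} has no negative examples")
    return (float(roc_auc_score(binary, scores)),
            float(average_precision_score(binary, scores)))


@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics plus overall accuracy."""

    per_class: dict[str, dict[str, float]]
    overall_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame.from_dict(self.per_class, orient="index")
        return frame.reindex(columns=list(METRIC_COLUMNS))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("class").to_csv(path, sep="\t")


def evaluate_predictions(
    probabilities: np.ndarray,
    true_labels: np.ndarray,
    class_names: Sequence[str] = LABELS,
) -> MetricsReport:
    """Full report from (n, n_classes) probabilities and integer truths."""
    probabilities = np.asarray(probabilities, dtype=float)
    true_labels = np.asarray(true_labels)
    predicted = probabilities.argmax(axis=1)
    per_class: dict[str, dict[str, float]] = {}
    for class_id, name in enumerate(class_names):
        metrics = class_metrics(confusion_counts(predicted, true_labels, class_id))
        if (true_labels == class_id).any() and not (true_labels == class_id).all():
            roc, pr = ranked_areas(probabilities[:, class_id], true_labels, class_id)
        else:
            warnings.warn(
                f"class {name} lacks positives or negatives; ROC/PR undefined, "
                "reporting 0", stacklevel=2,
            )
            roc, pr = 0.0, 0.0
        metrics["roc_auc"] = roc
        metrics["pr_auc"] = pr
        per_class[name] = metrics
    return MetricsReport(
        per_class=per_class,
        overall_accuracy=overall_accuracy(predicted, true_labels),
    )
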