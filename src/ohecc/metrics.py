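"""Confusion matrices and the four classification metrics.

Orientation: rows index the *predicted* class and columns the *true* class
(the transpose of the scikit-learn habit).  The positive class defaults to
the first-listed class of the task -- {0}, (R), "-" -- which is the unique
convention under which the published per-task metric tables agree with their
confusion matrices.  Both conventions are stated on every printed report.

With ``p`` the positive-class index:

* accuracy  = trace / total (any number of classes)
* precision = counts[p, p] / row-p sum   (that row holds everything
  *predicted* positive)
* recall    = counts[p, p] / column-p sum (that column holds everything
  *truly* positive)
* F1        = harmonic mean of precision and recall

Precision/recall/F1 are defined for binary matrices only; an empty row or
column makes the corresponding metric an explicit NaN with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class ConfusionMatrix:
    """k x k count table; ``counts[i, j]`` = predicted ``classes[i]``, true ``classes[j]``."""

    counts: np.ndarray
    classes: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.classes = tuple(self.classes)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts shape {self.counts.shape} does not match {k} classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def transpose(self) -> "ConfusionMatrix":
        """The same table with the orientation flipped (rows become true)."""
        return ConfusionMatrix(self.counts.T.copy(), self.classes)

    def to_frame(self) -> pd.DataFrame:
        """Printable table with explicit axis captions."""
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.classes, name="predicted"),
            columns=pd.Index(self.classes, name="true"),
        )


def confusion(true_labels: Sequence, predicted_labels: Sequence, classes: Sequence) -> ConfusionMatrix:
    """Count table in the predicted-by-true orientation."""
    classes = tuple(classes)
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if len(t) != len(p):
        raise ValueError(f"{len(t)} true labels vs {len(p)} predictions")
    pos = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    for ti, pi in zip(t.tolist(), p.tolist()):
        if ti not in pos:
            raise ValueError(f"true label {ti!r} not in classes {list(classes)}")
        if pi not in pos:
            raise ValueError(f"predicted label {pi!r} not in classes {list(classes)}")
        counts[pos[pi], pos[ti]] += 1
    return ConfusionMatrix(counts, classes)


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator", RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def metrics(cm: ConfusionMatrix, positive=None) -> dict[str, float]:
    """Accuracy, precision, recall and F1 at full precision.

    ``positive`` defaults to the first-listed class.  For matrices with more
    than two classes only accuracy is returned.
    """
    out = {"accuracy": _safe_div(float(np.trace(cm.counts)), float(cm.total), "accuracy")}
    if len(cm.classes) != 2:
        return out
    if positive is None:
        positive = cm.classes[0]
    if positive not in cm.classes:
        raise ValueError(f"positive class {positive!r} not in {cm.classes}")
    p = cm.classes.index(positive)
    tp = float(cm.counts[p, p])
    precision = _safe_div(tp, float(cm.counts[p, :].sum()), "precision")
    recall = _safe_div(tp, float(cm.counts[:, p].sum()), "recall")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
        if precision + recall == 0:
            warnings.warn("f1 undefined: precision + recall is zero", RuntimeWarning, stacklevel=2)
    else:
        f1 = 2 * precision * recall / (precision + recall)
    out.update({"precision": precision, "recall": recall, "f1": f1})
    return out


def round_metrics(values: dict[str, float], decimals: int = 3) -> dict[str, float]:
    """Round half-to-even at ``decimals`` places (for table comparison)."""
    return {k: float(np.round(v, decimals)) for k, v in values.items()}


def metrics_report(cm: ConfusionMatrix, positive=None) -> pd.DataFrame:
    """One-row accuracy/precision/recall/F1 table rounded to 3 decimals."""
    vals = round_metrics(metrics(cm, positive=positive))
    return pd.DataFrame([vals])
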