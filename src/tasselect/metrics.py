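"""Binary classification diagnostics.

Positive class = 1 = selective.  Two balanced-accuracy variants are
exposed: :func:`balanced_accuracy_pr` is the (precision + recall)/2 form
found in some applied workflows, :func:`balanced_accuracy_standard` is the
textbook (TPR + TNR)/2.  They are kept under distinct names to avoid silent
confusion.

Zero-denominator metrics return ``None`` (an explicit undefined marker)
rather than raising; the F1 of undefined precision/recall is reported as
0.0 so threshold grid searches remain total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _check_binary(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v)
    if not np.isin(v, (0, 1)).all():
        raise MetricsError(f"{name} must be binary 0/1")
    return v.astype(int)


def confusion(labels: np.ndarray, calls: np.ndarray) -> ConfusionCounts:
    labels = _check_binary(labels, "labels")
    calls = _check_binary(calls, "calls")
    if labels.shape != calls.shape:
        raise MetricsError("labels and calls must have equal length")
    return ConfusionCounts(
        tp=int(((labels == 1) & (calls == 1)).sum()),
        fp=int(((labels == 0) & (calls == 1)).sum()),
        tn=int(((labels == 0) & (calls == 0)).sum()),
        fn=int(((labels == 1) & (calls == 0)).sum()),
    )


def precision_recall_f1(
    c: ConfusionCounts,
) -> tuple[float | None, float | None, float | None]:
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    if precision is None or recall is None:
        f1 = 0.0  # undefined components: flagged as 0 for grid stability
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def balanced_accuracy_pr(c: ConfusionCounts) -> float | None:
    """(precision + recall) / 2 — a nonstandard balanced-accuracy variant
    in circulation; kept verbatim and clearly named."""
    precision, recall, _ = precision_recall_f1(c)
    if precision is None or recall is None:
        return None
    return (precision + recall) / 2


def balanced_accuracy_standard(c: ConfusionCounts) -> float | None:
    """(TPR + TNR) / 2, the textbook balanced accuracy."""
    tpr = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    tnr = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else None
    if tpr is None or tnr is None:
        return None
    return (tpr + tnr) / 2


def roc_curve_auc(
    labels: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points at every distinct score threshold plus trapezoidal AUC."""
    labels = _check_binary(labels, "labels")
    if len(np.unique(labels)) < 2:
        raise MetricsError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def f1_curve(
    labels: np.ndarray, scores: np.ndarray, grid_step: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """F1 at each grid threshold in (0, 1) with the >= call convention."""
    labels = _check_binary(labels, "labels")
    if len(np.unique(labels)) < 2:
        raise MetricsError("F1 curve requires both classes present")
    scores = np.asarray(scores, dtype=float)
    grid = np.arange(grid_step, 1.0, grid_step)
    f1s = np.empty_like(grid)
    for i, t in enumerate(grid):
        _, _, f1 = precision_recall_f1(confusion(labels, (scores >= t).astype(int)))
        f1s[i] = 0.0 if f1 is None else f1
    return grid, f1s


def pr_curve(
    labels: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Precision-recall points swept over the distinct score thresholds."""
    labels = _check_binary(labels, "labels")
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="mergesort")
    labels = labels[order]
    tp = np.cumsum(labels)
    fp = np.cumsum(1 - labels)
    n_pos = labels.sum()
    if n_pos == 0:
        raise MetricsError("PR curve requires positive examples")
    # keep the last point per distinct score
    distinct = np.flatnonzero(np.diff(scores[order], append=-np.inf))
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    recall = tp[distinct] / n_pos
    return precision, recall


def score_histogram(
    scores: np.ndarray, n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram of scores on [0, 1]; counts conserve n."""
    scores = np.asarray(scores, dtype=float)
    if ((scores < 0) | (scores > 1)).any():
        raise MetricsError("scores must lie in [0, 1]")
    counts, edges = np.histogram(scores, bins=n_bins, range=(0.0, 1.0))
    return edges, counts


def metrics_report(
    labels: np.ndarray, scores: np.ndarray, decision_threshold: float = 0.5
) -> dict:
    """One-stop summary at a given decision threshold."""
    calls = (np.asarray(scores, dtype=float) >= decision_threshold).astype(int)
    c = confusion(labels, calls)
    precision, recall, f1 = precision_recall_f1(c)
    _, _, auc = roc_curve_auc(labels, scores)
    return {
        "tp": c.tp,
        "fp": c.fp,
        "tn": c.tn,
        "fn": c.fn,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "balanced_accuracy_pr": balanced_accuracy_pr(c),
        "balanced_accuracy_standard": balanced_accuracy_standard(c),
        "roc_auc": auc,
        "decision_threshold": decision_threshold,
    }
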