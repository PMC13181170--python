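"""Target-agnostic selectivity (TAS) aggregation and score binarization.

TAS collapses the per-threshold selectivity scores into one number: the
(optionally weighted) mean across thresholds.  A high TAS means the ligand
is predicted to bind few proteins at any affinity level of practical
relevance; a low TAS flags promiscuity.  Binary calls use per-head decision
thresholds; the published F1-optimal defaults for the 7.0/7.5/8.0/8.5 heads
are 0.36, 0.35, 0.27 and 0.33.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import confusion, precision_recall_f1

#: F1-optimal decision thresholds for the standard heads
DEFAULT_DECISION_THRESHOLDS: dict[float, float] = {
    7.0: 0.36,
    7.5: 0.35,
    8.0: 0.27,
    8.5: 0.33,
}
FALLBACK_DECISION_THRESHOLD = 0.5


class ScoringError(ValueError):
    pass


@dataclass
class TASResult:
    """Per-ligand threshold scores plus the aggregated TAS value."""

    threshold_scores: np.ndarray  # (n_ligands, n_thresholds) in [0, 1]
    tas: np.ndarray  # (n_ligands,)
    thresholds: tuple[float, ...]
    calls: np.ndarray | None = None
    decision_thresholds: np.ndarray | None = None


def tas_score(
    threshold_scores: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Mean of the per-threshold scores; a weighted mean when weights given.

    Accepts a single score vector (1-D) or a ligand x threshold array
    (2-D, averaged along the threshold axis).
    """
    s = np.asarray(threshold_scores, dtype=float)
    if s.size == 0:
        raise ScoringError("empty score vector")
    if weights is None:
        return s.mean(axis=-1)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ScoringError("weights must be non-negative with positive sum")
    return (s * w).sum(axis=-1) / w.sum()


def decision_thresholds_for(thresholds: tuple[float, ...]) -> np.ndarray:
    return np.array(
        [
            DEFAULT_DECISION_THRESHOLDS.get(t, FALLBACK_DECISION_THRESHOLD)
            for t in thresholds
        ]
    )


def binarize_scores(
    scores: np.ndarray, decision_thresholds: np.ndarray
) -> np.ndarray:
    """call = 1 iff score >= decision threshold for its head (ties inclusive)."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(decision_thresholds, dtype=float)
    if s.shape[-1] != t.shape[-1]:
        raise ScoringError(
            f"{s.shape[-1]} score heads vs {t.shape[-1]} decision thresholds"
        )
    if ((t <= 0) | (t >= 1)).any():
        raise ScoringError("decision thresholds must lie in (0, 1)")
    return (s >= t).astype(np.int8)


def score_ligands(
    threshold_scores: np.ndarray,
    thresholds: tuple[float, ...],
    *,
    binarize: bool = False,
    tas_weights: np.ndarray | None = None,
    binarize_before_average: bool = False,
) -> TASResult:
    """Assemble a :class:`TASResult` from model head scores.

    By default TAS averages the continuous head scores; set
    ``binarize_before_average`` to average the binary calls instead (the
    training-label semantics of the score).
    """
    s = np.atleast_2d(np.asarray(threshold_scores, dtype=float))
    dt = decision_thresholds_for(thresholds)
    calls = binarize_scores(s, dt) if (binarize or binarize_before_average) else None
    basis = calls.astype(float) if binarize_before_average else s
    return TASResult(
        threshold_scores=s,
        tas=tas_score(basis, tas_weights),
        thresholds=thresholds,
        calls=calls,
        decision_thresholds=dt,
    )


def optimal_decision_threshold(
    scores: np.ndarray, labels: np.ndarray, grid_step: float = 0.01
) -> tuple[float, float]:
    """Exhaustive grid search for the F1-maximizing decision threshold.

    Returns (threshold, best F1); the smallest maximizing grid point wins
    ties.  Raises for single-class labels, where F1 is undefined.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ScoringError("labels are single-class; F1 search undefined")
    best_t, best_f1 = 0.0, -1.0
    for t in np.arange(grid_step, 1.0, grid_step):
        calls = (scores >= t).astype(int)
        _, _, f1 = precision_recall_f1(confusion(labels, calls))
        f1 = 0.0 if f1 is None else f1
        if f1 > best_f1 + 1e-12:
            best_t, best_f1 = float(round(t, 10)), f1
    return best_t, best_f1


def calibration_table(
    scores: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> list[dict]:
    """Equal-width reliability bins over [0, 1].

    Each entry reports the bin edges, mean score, empirical positive rate
    (None for empty bins) and count.
    """
    if n_bins < 2:
        raise ScoringError("n_bins must be >= 2")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(scores, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        n = int(mask.sum())
        rows.append(
            {
                "bin_low": float(edges[b]),
                "bin_high": float(edges[b + 1]),
                "mean_score": float(scores[mask].mean()) if n else None,
                "positive_rate": float(labels[mask].mean()) if n else None,
                "count": n,
            }
        )
    return rows
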