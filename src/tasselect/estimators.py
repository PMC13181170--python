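"""Selectivity estimators and the cross-method Spearman harness.

Three routes to a per-ligand selectivity estimate are compared:

* ``model_tas`` — scores from the trained sequence model;
* ``cross_prediction`` — fraction of a dense predicted affinity matrix
  exceeding the threshold, over all proteins;
* ``experimental`` — fraction of measured affinities exceeding the
  threshold among the ligand's measured proteins, restricted to ligands
  with sufficient coverage (>= 10 distinct proteins by default).

Exceed-fractions rise with promiscuity, while model scores rise with
selectivity; for cross-method comparison the fractions are re-oriented as
1 - fraction by default (the mode is recorded in the report).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .affinity import AffinityMatrix, AffinityRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_MEASUREMENTS = 10

Method = Literal["model_tas", "cross_prediction", "experimental"]
METHODS: tuple[Method, ...] = ("model_tas", "cross_prediction", "experimental")


class EstimatorError(ValueError):
    pass


@dataclass
class EstimateFrame:
    """Per-ligand selectivity estimates for one method."""

    method: Method
    estimates: pd.DataFrame  # index ligand_id, columns est_<tau>
    thresholds: tuple[float, ...]
    coverage: pd.Series | None = None  # measured/predicted proteins per ligand
    orientation: str = "selectivity"  # high value = selective

    @property
    def threshold_agnostic(self) -> pd.Series:
        """Mean estimate across thresholds per ligand."""
        return self.estimates.mean(axis=1)


@dataclass
class CorrelationReport:
    per_threshold: dict[float, pd.DataFrame]  # 3x3 Spearman matrices
    overall: pd.DataFrame  # methods + threshold-agnostic columns
    n_ligands: dict[str, int] = field(default_factory=dict)
    orientation_mode: str = "one_minus_fraction"


def filter_min_measurements(
    records: Iterable[AffinityRecord],
    min_count: int = DEFAULT_MIN_MEASUREMENTS,
) -> tuple[set[str], set[str]]:
    """Keep ligands measured against >= min_count distinct proteins.

    Returns (retained ligands, proteins appearing in the retained records).
    """
    if min_count < 1:
        raise EstimatorError("min_count must be >= 1")
    per_ligand: dict[str, set[str]] = {}
    for r in records:
        per_ligand.setdefault(r.ligand_id, set()).add(r.protein_id)
    ligands = {l for l, prots in per_ligand.items() if len(prots) >= min_count}
    proteins = set().union(*(per_ligand[l] for l in ligands)) if ligands else set()
    if not ligands:
        logger.warning("no ligand has >= %d distinct-protein measurements", min_count)
    return ligands, proteins


def exceed_fraction_estimate(
    matrix: AffinityMatrix,
    threshold: float,
    denominator: Literal["all_proteins", "measured_proteins"] = "measured_proteins",
) -> pd.Series:
    """Per-ligand fraction of affinities strictly above the threshold.

    ``all_proteins`` divides by the full protein panel (dense predicted
    matrices); ``measured_proteins`` divides by each ligand's observed
    count (sparse experimental matrices).  Ligands with no observations are
    excluded under ``measured_proteins``.
    """
    observed = matrix.observed_mask
    exceed = np.where(observed, matrix.values > threshold, False).sum(axis=1)
    if denominator == "all_proteins":
        if not observed.all():
            raise EstimatorError(
                "all_proteins denominator requires a fully observed matrix"
            )
        frac = exceed / matrix.n_proteins
        idx = matrix.ligand_ids
    else:
        counts = observed.sum(axis=1)
        keep = counts > 0
        dropped = [l for l, k in zip(matrix.ligand_ids, keep) if not k]
        if dropped:
            logger.info(
                "%d ligands with zero measured proteins excluded (e.g. %s)",
                len(dropped), dropped[:3],
            )
        frac = exceed[keep] / counts[keep]
        idx = [l for l, k in zip(matrix.ligand_ids, keep) if k]
    return pd.Series(frac, index=pd.Index(idx, name="ligand_id"))


def orient_as_selectivity(
    fractions: pd.Series | np.ndarray,
    mode: Literal["raw_fraction", "one_minus_fraction", "negated_rank"] = "one_minus_fraction",
):
    """Turn an exceed-fraction (high = promiscuous) into a selectivity scale."""
    if mode == "raw_fraction":
        return fractions
    if mode == "one_minus_fraction":
        return 1.0 - fractions
    if mode == "negated_rank":
        return -np.asarray(fractions, dtype=float)
    raise EstimatorError(f"unknown orientation mode {mode!r}")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Pairwise-complete: entries where either side is NaN are dropped.
    Returns NaN (the undefined marker) when either vector has zero variance
    or fewer than 3 complete pairs remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise EstimatorError("vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def estimate_from_matrix(
    matrix: AffinityMatrix,
    thresholds: tuple[float, ...],
    method: Method,
    *,
    denominator: Literal["all_proteins", "measured_proteins"] | None = None,
    orientation: str = "one_minus_fraction",
) -> EstimateFrame:
    """Build an exceed-fraction EstimateFrame for one matrix."""
    if denominator is None:
        denominator = (
            "all_proteins" if method == "cross_prediction" else "measured_proteins"
        )
    cols = {}
    for tau in thresholds:
        frac = exceed_fraction_estimate(matrix, tau, denominator)
        cols[f"est_{tau}"] = orient_as_selectivity(frac, orientation)
    df = pd.DataFrame(cols)
    coverage = pd.Series(
        matrix.observed_mask.sum(axis=1),
        index=pd.Index(matrix.ligand_ids, name="ligand_id"),
    ).reindex(df.index)
    return EstimateFrame(method, df, thresholds, coverage, orientation)


def correlation_test(
    frames: dict[Method, EstimateFrame], thresholds: tuple[float, ...]
) -> CorrelationReport:
    """Pairwise Spearman matrices across methods, per threshold and overall.

    All comparisons run on the intersection of ligand ids across the
    supplied frames; the intersection size is recorded.
    """
    keys = list(frames)
    common = None
    for f in frames.values():
        ids = set(f.estimates.index)
        common = ids if common is None else (common & ids)
    if not common:
        raise EstimatorError("no common ligands across the supplied methods")
    common_idx = sorted(common)
    if len(common_idx) < 3:
        raise EstimatorError(
            f"only {len(common_idx)} common ligands; need >= 3 for correlation"
        )

    per_threshold: dict[float, pd.DataFrame] = {}
    for tau in thresholds:
        col = f"est_{tau}"
        vecs = {m: frames[m].estimates.loc[common_idx, col] for m in keys}
        per_threshold[tau] = _rho_matrix(vecs, keys)

    overall_vecs: dict[str, pd.Series] = {}
    for m in keys:
        for tau in thresholds:
            overall_vecs[f"{m}_{tau}"] = frames[m].estimates.loc[common_idx, f"est_{tau}"]
        overall_vecs[f"{m}_agnostic"] = frames[m].threshold_agnostic.loc[common_idx]
    overall = _rho_matrix(overall_vecs, list(overall_vecs))

    return CorrelationReport(
        per_threshold=per_threshold,
        overall=overall,
        n_ligands={"intersection": len(common_idx)},
        orientation_mode=next(iter(frames.values())).orientation,
    )


def _rho_matrix(vecs: dict, names: list) -> pd.DataFrame:
    k = len(names)
    mat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rho = spearman_rho(vecs[names[i]], vecs[names[j]])
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=names, columns=names)


def threshold_agnostic_consistency(
    threshold_scores: pd.DataFrame, tas: pd.Series | None = None
) -> pd.Series:
    """Spearman(TAS, per-threshold score) for each threshold column.

    With no ``tas`` given, the row mean of the score columns is used.
    """
    if len(threshold_scores) < 3:
        raise EstimatorError("need >= 3 ligands")
    if tas is None:
        tas = threshold_scores.mean(axis=1)
    return pd.Series(
        {c: spearman_rho(tas, threshold_scores[c]) for c in threshold_scores.columns}
    )
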