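"""Selectivity label construction from an affinity matrix.

Pipeline (per ligand): count the proteins bound above each affinity
threshold, drop thresholds whose count column is almost entirely zero,
binarize the remaining counts against their column mean (at or below the
mean = selective = 1), and derive inverse-class-frequency sample weights
normalized to unit mean.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .affinity import AffinityMatrix

logger = logging.getLogger(__name__)

#: thresholds on the combined -log10 molar affinity; 9.0 is routinely pruned
#: on sparse data
DEFAULT_THRESHOLDS: tuple[float, ...] = (7.0, 7.5, 8.0, 8.5, 9.0)
DEFAULT_ZERO_FRACTION_CUTOFF = 0.95


class LabelBuildError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdSet:
    """Strictly increasing affinity cutoffs."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        t = self.thresholds
        if not t:
            raise LabelBuildError("threshold set is empty")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise LabelBuildError(f"thresholds not strictly increasing: {t}")

    def __iter__(self):
        return iter(self.thresholds)

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass
class BindingCountTable:
    """Per-ligand, per-threshold counts of proteins bound above threshold."""

    ligand_ids: list[str]
    thresholds: ThresholdSet
    counts: np.ndarray  # (n_ligands, n_thresholds) int

    @property
    def column_means(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    @property
    def zero_fraction(self) -> np.ndarray:
        return (self.counts == 0).mean(axis=0)


@dataclass
class PruneReport:
    dropped: list[tuple[float, float]]  # (threshold, zero_fraction)
    retained: list[tuple[float, float]]


@dataclass
class SelectivityLabelSet:
    """Binary selectivity labels (1 = selective) plus training weights."""

    ligand_ids: list[str]
    smiles: list[str]
    retained_thresholds: ThresholdSet
    labels: np.ndarray  # (n_ligands, n_retained) in {0, 1}
    weights: np.ndarray  # (n_ligands,), mean 1
    column_means: np.ndarray  # binarization cutoffs per retained threshold
    prune_report: PruneReport | None = None

    @property
    def class_fractions(self) -> np.ndarray:
        """Per-threshold fraction of label 0 (nonselective)."""
        return (self.labels == 0).mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"smiles": self.smiles})
        for k, tau in enumerate(self.retained_thresholds):
            df[f"sel_{tau}"] = self.labels[:, k].astype(int)
        df["weight"] = self.weights
        df.index = pd.Index(self.ligand_ids, name="ligand_id")
        return df

    def save(self, csv_path: str | Path) -> None:
        """Write the training-table CSV plus a JSON sidecar of build facts."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path)
        sidecar = {
            "thresholds": list(self.retained_thresholds),
            "column_means": self.column_means.tolist(),
            "class_fractions_label0": self.class_fractions.tolist(),
            "n_ligands": len(self.ligand_ids),
        }
        if self.prune_report is not None:
            sidecar["pruned"] = [
                {"threshold": t, "zero_fraction": z}
                for t, z in self.prune_report.dropped
            ]
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def count_bindings(
    matrix: AffinityMatrix, thresholds: ThresholdSet | None = None
) -> BindingCountTable:
    """n[i, t] = number of observed affinities of ligand i strictly above tau_t."""
    thresholds = thresholds or ThresholdSet()
    vals = matrix.values[:, :, None]  # (L, P, 1)
    taus = np.asarray(list(thresholds))[None, None, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN comparisons
        exceeded = vals > taus  # NaN > tau is False: missing never counted
    counts = exceeded.sum(axis=1).astype(int)
    return BindingCountTable(list(matrix.ligand_ids), thresholds, counts)


def prune_sparse_thresholds(
    table: BindingCountTable,
    zero_fraction_cutoff: float = DEFAULT_ZERO_FRACTION_CUTOFF,
) -> tuple[ThresholdSet, PruneReport]:
    """Drop thresholds whose count column is >= cutoff zeros.

    A column that is almost all zeros carries no trainable signal (on the
    reference data 98% of ligands bound nothing above 9.0, so that threshold
    was excluded).
    """
    if not 0 < zero_fraction_cutoff <= 1:
        raise LabelBuildError("zero_fraction_cutoff must be in (0, 1]")
    zf = table.zero_fraction
    dropped, retained = [], []
    for tau, z in zip(table.thresholds, zf):
        (dropped if z >= zero_fraction_cutoff else retained).append((tau, float(z)))
    if not retained:
        raise LabelBuildError(
            "all thresholds pruned as too sparse; lower the thresholds or "
            f"the cutoff (zero fractions: {dict(dropped)})"
        )
    for tau, z in dropped:
        logger.info("pruning threshold %.1f (zero fraction %.3f)", tau, z)
    return (
        ThresholdSet(tuple(t for t, _ in retained)),
        PruneReport(dropped, retained),
    )


def binarize_by_column_mean(
    table: BindingCountTable, retained: ThresholdSet | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Binarize counts against their column mean: count <= mean -> 1 (selective).

    Ties go to the selective class: a ligand sitting exactly at average
    promiscuity is not flagged as promiscuous.  Returns (labels, column_means).
    """
    retained = retained or table.thresholds
    idx = [table.thresholds.thresholds.index(t) for t in retained]
    counts = table.counts[:, idx]
    means = counts.mean(axis=0)
    labels = (counts <= means[None, :]).astype(np.int8)
    return labels, means


def compute_sample_weights(labels: np.ndarray) -> np.ndarray:
    """Rarity-emphasizing per-ligand weights from a binary label table.

    Per column, each ligand gets the inverse empirical frequency of its own
    label value, rescaled so the column's mean weight is 1; the per-column
    weights are averaged across columns and the final vector renormalized to
    mean exactly 1.  Rarer selectivity profiles thus weigh more.  A
    single-class column is uninformative and contributes weight 1 everywhere.
    """
    labels = np.asarray(labels)
    if labels.ndim == 1:
        labels = labels[:, None]
    if labels.size == 0:
        raise LabelBuildError("empty label table")
    n, t = labels.shape
    colw = np.ones((n, t))
    for j in range(t):
        col = labels[:, j]
        f1 = col.mean()
        f0 = 1.0 - f1
        if f0 == 0.0 or f1 == 0.0:
            warnings.warn(
                f"label column {j} is single-class; weights set to 1",
                stacklevel=2,
            )
            continue
        # inverse class frequency; 1/(2f) has unit mean over the column
        w = np.where(col == 1, 1.0 / (2.0 * f1), 1.0 / (2.0 * f0))
        colw[:, j] = w / w.mean()
    weights = colw.mean(axis=1)
    weights = weights / weights.mean()
    return weights


def build_training_table(
    matrix: AffinityMatrix,
    thresholds: ThresholdSet | None = None,
    zero_fraction_cutoff: float = DEFAULT_ZERO_FRACTION_CUTOFF,
) -> SelectivityLabelSet:
    """Full label construction: counts -> prune -> binarize -> weights.

    Column means are computed on the full ligand set before any train/test
    split.
    """
    table = count_bindings(matrix, thresholds)
    retained, report = prune_sparse_thresholds(table, zero_fraction_cutoff)
    labels, means = binarize_by_column_mean(table, retained)
    weights = compute_sample_weights(labels)
    smiles = [matrix.smiles_for(l) or l for l in matrix.ligand_ids]
    return SelectivityLabelSet(
        ligand_ids=list(matrix.ligand_ids),
        smiles=smiles,
        retained_thresholds=retained,
        labels=labels,
        weights=weights,
        column_means=means,
        prune_report=report,
    )


def split_train_test(
    table: pd.DataFrame, test_fraction: float = 0.05, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded ligand-level holdout split (train, test)."""
    if not 0 < test_fraction < 1:
        raise LabelBuildError("test_fraction must be in (0, 1)")
    n = len(table)
    n_test = round(n * test_fraction)
    if n_test == 0 or n_test == n:
        raise LabelBuildError(
            f"table of {n} rows too small for test_fraction={test_fraction}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return table.iloc[train_idx], table.iloc[test_idx]


def load_training_table(csv_path: str | Path) -> pd.DataFrame:
    """Read a training-table CSV (smiles, sel_<tau>..., weight)."""
    df = pd.read_csv(csv_path, index_col=0)
    if "smiles" not in df.columns or "weight" not in df.columns:
        raise LabelBuildError(
            f"{csv_path}: expected 'smiles' and 'weight' columns"
        )
    return df


def label_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("sel_")]
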