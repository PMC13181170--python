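"""Reading, validation and matrix assembly for ligand-protein affinity data.

The working unit of affinity throughout the package is a single number on the
-log10 molar scale.  Measured or predicted pKi and pIC50 are close numerically
despite their different nature, and downstream steps only ever compare the
value against thresholds, so the two are collapsed into one *combined
affinity*: the arithmetic mean when both are present, the present value when
only one is (configurable to a strict both-required mode).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sanity bound for affinities on the -log10 molar scale
AFFINITY_RANGE: tuple[float, float] = (0.0, 15.0)

Provenance = Literal["predicted", "experimental"]


class AffinityValidationError(ValueError):
    """A record or table failed validation; the message names the offender."""


@dataclass(frozen=True)
class AffinityRecord:
    """One ligand-protein affinity observation (long format)."""

    ligand_id: str
    smiles: str
    protein_id: str
    pki: float | None = None
    pic50: float | None = None
    provenance: Provenance = "experimental"

    def __post_init__(self) -> None:
        if not self.smiles:
            raise AffinityValidationError(
                f"record ({self.ligand_id}, {self.protein_id}): empty SMILES"
            )
        if self.pki is None and self.pic50 is None:
            raise AffinityValidationError(
                f"record ({self.ligand_id}, {self.protein_id}): "
                "both pKi and pIC50 missing"
            )
        lo, hi = AFFINITY_RANGE
        for name, v in (("pKi", self.pki), ("pIC50", self.pic50)):
            if v is not None and not (math.isfinite(v) and lo <= v <= hi):
                raise AffinityValidationError(
                    f"record ({self.ligand_id}, {self.protein_id}): "
                    f"{name}={v!r} outside [{lo}, {hi}]"
                )

    @property
    def combined(self) -> float:
        return combine_affinity(self.pki, self.pic50)


def combine_affinity(
    pki: float | None,
    pic50: float | None,
    *,
    require_both: bool = False,
) -> float:
    """Collapse pKi/pIC50 into the single working affinity (pKi + pIC50)/2.

    When exactly one value is present it is used as-is unless
    ``require_both`` is set (sparse experimental sources rarely report both;
    discarding single-value records would bias experimental estimates).
    """
    if pki is None and pic50 is None:
        raise AffinityValidationError("both pKi and pIC50 missing")
    if pki is None or pic50 is None:
        if require_both:
            raise AffinityValidationError(
                "strict mode requires both pKi and pIC50"
            )
        return float(pki if pki is not None else pic50)  # type: ignore[arg-type]
    return (float(pki) + float(pic50)) / 2.0


@dataclass
class AffinityMatrix:
    """Ligand x protein combined-affinity matrix with explicit missingness.

    Rows follow ``ligand_ids``, columns follow ``protein_ids``; both are
    sorted lexicographically at construction for reproducibility.  Missing
    cells are NaN.
    """

    ligand_ids: list[str]
    protein_ids: list[str]
    values: np.ndarray  # (n_ligands, n_proteins), NaN = missing
    smiles: dict[str, str] = field(default_factory=dict)
    provenance: Provenance = "experimental"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ligand_ids), len(self.protein_ids)):
            raise AffinityValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.ligand_ids)} ligands x {len(self.protein_ids)} proteins"
            )

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def smiles_for(self, ligand_id: str) -> str:
        return self.smiles.get(ligand_id, "")

    def to_records(self) -> list[AffinityRecord]:
        """Flatten back to long format.

        The combined value is stored in both affinity slots so that a
        round-trip through :func:`build_matrix` reproduces the cells exactly.
        """
        out: list[AffinityRecord] = []
        for i, lig in enumerate(self.ligand_ids):
            for j, prot in enumerate(self.protein_ids):
                v = self.values[i, j]
                if not np.isnan(v):
                    out.append(
                        AffinityRecord(
                            ligand_id=lig,
                            smiles=self.smiles.get(lig, lig),
                            protein_id=prot,
                            pki=float(v),
                            pic50=float(v),
                            provenance=self.provenance,
                        )
                    )
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.ligand_ids, columns=self.protein_ids
        )


DEFAULT_COLUMNS = {
    "ligand_id": "ligand_id",
    "smiles": "smiles",
    "protein_id": "protein_id",
    "pki": "pki",
    "pic50": "pic50",
    "provenance": "provenance",
}


@dataclass
class LoadReport:
    n_accepted: int
    n_rejected: int
    rejects: list[tuple[int, str]]  # (row number, reason)


def load_affinity_table(
    path: str | Path,
    *,
    columns: dict[str, str] | None = None,
    sep: str = ",",
    default_provenance: Provenance = "experimental",
) -> tuple[list[AffinityRecord], LoadReport]:
    """Load a long-format CSV/TSV of affinity records.

    Every row either yields a valid :class:`AffinityRecord` or is reported
    with its row number and reason.  Duplicate (ligand, protein) pairs are
    kept; deduplication happens at :func:`build_matrix`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"affinity table not found: {path}")
    colmap = dict(DEFAULT_COLUMNS, **(columns or {}))
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    mandatory = [colmap["ligand_id"], colmap["smiles"], colmap["protein_id"]]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise AffinityValidationError(
            f"{path}: missing mandatory columns {missing}; found {list(df.columns)}"
        )
    has_prov = colmap["provenance"] in df.columns

    records: list[AffinityRecord] = []
    rejects: list[tuple[int, str]] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header=1
        d = dict(zip(df.columns, row))
        try:
            pki = _parse_float(d.get(colmap["pki"], ""))
            pic50 = _parse_float(d.get(colmap["pic50"], ""))
            prov = d.get(colmap["provenance"], "") if has_prov else ""
            records.append(
                AffinityRecord(
                    ligand_id=d[colmap["ligand_id"]],
                    smiles=d[colmap["smiles"]],
                    protein_id=d[colmap["protein_id"]],
                    pki=pki,
                    pic50=pic50,
                    provenance=prov or default_provenance,  # type: ignore[arg-type]
                )
            )
        except (AffinityValidationError, ValueError) as exc:
            rejects.append((idx, str(exc)))
    report = LoadReport(len(records), len(rejects), rejects)
    logger.info(
        "loaded %s: %d accepted, %d rejected", path, report.n_accepted,
        report.n_rejected,
    )
    return records, report


def _parse_float(s: str) -> float | None:
    s = (s or "").strip()
    if not s:
        return None
    return float(s)


def write_affinity_table(matrix: AffinityMatrix, path: str | Path) -> None:
    """Write a matrix back to the long-format CSV schema."""
    rows = [
        {
            "ligand_id": r.ligand_id,
            "smiles": r.smiles,
            "protein_id": r.protein_id,
            "pki": r.pki,
            "pic50": r.pic50,
            "provenance": r.provenance,
        }
        for r in matrix.to_records()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def canonicalize_smiles(smiles: str) -> str:
    """Canonical form via RDKit; raises if RDKit is unavailable or parse fails."""
    from rdkit import Chem  # optional dependency

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise AffinityValidationError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def build_matrix(
    records: Iterable[AffinityRecord],
    *,
    dedupe: Literal["mean", "max", "error"] = "mean",
    require_both: bool = False,
    provenance: Provenance | None = None,
) -> AffinityMatrix:
    """Assemble the ligand x protein combined-affinity matrix.

    Duplicate (ligand, protein) measurements are resolved by ``dedupe``:
    ``mean`` averages the combined affinities, ``max`` keeps the strongest,
    ``error`` refuses and lists the offending pairs.
    """
    records = list(records)
    if not records:
        raise AffinityValidationError("no records to build a matrix from")

    cells: dict[tuple[str, str], list[float]] = {}
    smiles: dict[str, str] = {}
    for r in records:
        cells.setdefault((r.ligand_id, r.protein_id), []).append(
            combine_affinity(r.pki, r.pic50, require_both=require_both)
        )
        smiles.setdefault(r.ligand_id, r.smiles)

    dupes = [k for k, v in cells.items() if len(v) > 1]
    if dupes and dedupe == "error":
        raise AffinityValidationError(
            f"{len(dupes)} duplicated (ligand, protein) pairs, e.g. {dupes[:5]}"
        )
    reduce = np.mean if dedupe == "mean" else np.max

    ligand_ids = sorted({lig for lig, _ in cells})
    protein_ids = sorted({prot for _, prot in cells})
    li = {l: i for i, l in enumerate(ligand_ids)}
    pj = {p: j for j, p in enumerate(protein_ids)}
    values = np.full((len(ligand_ids), len(protein_ids)), np.nan)
    for (lig, prot), vals in cells.items():
        values[li[lig], pj[prot]] = reduce(vals)

    if provenance is None:
        provs = {r.provenance for r in records}
        provenance = "predicted" if provs == {"predicted"} else "experimental"
    return AffinityMatrix(ligand_ids, protein_ids, values, smiles, provenance)
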