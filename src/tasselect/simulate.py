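"""Synthetic ligand-protein universes with known ground truth.

The generator emulates the two data regimes the pipeline consumes: a dense
"predicted" affinity matrix (every ligand scored against every protein) and
a sparse, coverage-biased "experimental" subset of it.  Each ligand carries
a latent promiscuity pi in (0, 1); each protein a latent druggability.
Affinity follows an additive model on the -log10 molar scale,

    a[i, p] = mu + alpha * logit(pi_i) + beta * d_p + eps,  eps ~ N(0, sigma^2),

clipped to [3, 12] so values straddle the 7.0-8.5 working thresholds.
Promiscuity is drawn from a two-component Beta mixture (selective-rich vs
promiscuous-rich) so the derived labels show the strong class imbalance
seen in real affinity panels.  SMILES are assembled from a small fragment
grammar in which aromatic-ring and halogen content grows with the
promiscuity decile, giving the token composition a learnable, monotone
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .affinity import AffinityMatrix

AFFINITY_CLIP = (3.0, 12.0)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class UniverseParams:
    """Generator knobs; the defaults mirror the imbalanced, mostly
    selective composition of real proteome-wide panels."""

    n_ligands: int = 1000
    n_proteins: int = 100
    baseline_mu: float = 7.0
    ligand_effect_alpha: float = 0.9
    protein_effect_beta: float = 1.2
    noise_sigma: float = 0.4
    missing_rate: float = 0.5
    coverage_bias: float = 0.5
    selective_weight: float = 0.85
    beta_selective: tuple[float, float] = (2.0, 5.0)
    beta_promiscuous: tuple[float, float] = (6.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ligands < 2 or self.n_proteins < 2:
            raise SimulationError("need at least 2 ligands and 2 proteins")
        if self.noise_sigma < 0:
            raise SimulationError("noise_sigma must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise SimulationError("missing_rate must be in [0, 1)")
        if not 0 < self.selective_weight <= 1:
            raise SimulationError("selective_weight must be in (0, 1]")


@dataclass
class SyntheticUniverse:
    params: UniverseParams
    ligand_ids: list[str]
    protein_ids: list[str]
    pi: np.ndarray  # latent promiscuity per ligand
    druggability: np.ndarray  # latent effect per protein
    dense_matrix: AffinityMatrix  # provenance=predicted, fully observed
    sparse_matrix: AffinityMatrix  # provenance=experimental
    smiles: dict[str, str] = field(default_factory=dict)
    aromatic_fraction: np.ndarray | None = None

    def ground_truth_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "ligand_id": self.ligand_ids,
                "pi": self.pi,
                "selectivity": 1.0 - self.pi,
            }
        )
        if self.aromatic_fraction is not None:
            df["aromatic_fraction"] = self.aromatic_fraction
        return df.set_index("ligand_id")

    def save(self, directory: str | Path) -> None:
        from .affinity import write_affinity_table

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_affinity_table(self.dense_matrix, directory / "dense_predicted.csv")
        write_affinity_table(self.sparse_matrix, directory / "sparse_experimental.csv")
        self.ground_truth_frame().to_csv(directory / "ground_truth.csv")


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def generate_universe(
    params: UniverseParams | None = None, *, with_smiles: bool = True, **overrides
) -> SyntheticUniverse:
    """Draw a reproducible universe under ``params`` (or keyword overrides)."""
    params = replace(params or UniverseParams(), **overrides)
    rng = np.random.default_rng(params.seed)
    n, p = params.n_ligands, params.n_proteins

    is_promiscuous = rng.random(n) >= params.selective_weight
    a1, b1 = params.beta_selective
    a2, b2 = params.beta_promiscuous
    pi = np.where(
        is_promiscuous, rng.beta(a2, b2, size=n), rng.beta(a1, b1, size=n)
    )
    pi = np.clip(pi, 1e-4, 1 - 1e-4)
    drug = rng.normal(0.0, 1.0, size=p)

    affinity = (
        params.baseline_mu
        + params.ligand_effect_alpha * _logit(pi)[:, None]
        + params.protein_effect_beta * drug[None, :]
        + rng.normal(0.0, params.noise_sigma, size=(n, p))
    )
    affinity = np.clip(affinity, *AFFINITY_CLIP)

    width = len(str(n - 1))
    ligand_ids = [f"L{str(i).zfill(width)}" for i in range(n)]
    protein_ids = [f"P{str(j).zfill(len(str(p - 1)))}" for j in range(p)]

    universe = SyntheticUniverse(
        params=params,
        ligand_ids=ligand_ids,
        protein_ids=protein_ids,
        pi=pi,
        druggability=drug,
        dense_matrix=AffinityMatrix(
            ligand_ids, protein_ids, affinity, {}, provenance="predicted"
        ),
        sparse_matrix=AffinityMatrix(
            ligand_ids, protein_ids, affinity.copy(), {}, provenance="experimental"
        ),
    )
    universe.sparse_matrix = sparsify(
        universe.dense_matrix,
        params.missing_rate,
        params.coverage_bias,
        seed=params.seed + 1,
    )
    if with_smiles:
        attach_smiles(universe, seed=params.seed + 2)
    return universe


def attach_smiles(universe: SyntheticUniverse, seed: int = 0) -> SyntheticUniverse:
    """Assemble fragment-grammar SMILES whose aromatic content tracks pi.

    Promiscuity decile d maps to d // 3 benzene rings and d // 4 halogen
    branches on an alkyl chain whose length shrinks with d, so the
    aromatic-token fraction is (noisily) monotone in pi.  The bottom decile
    is a plain single chain with no halogens.  All strings tokenize within
    the model's length budget.
    """
    rng = np.random.default_rng(seed)
    smiles: dict[str, str] = {}
    arom = np.empty(len(universe.ligand_ids))
    for i, (lig, pi) in enumerate(zip(universe.ligand_ids, universe.pi)):
        decile = min(9, int(pi * 10))
        n_rings = decile // 3
        n_hal = decile // 4
        chain = 2 + (9 - decile) + int(rng.integers(0, 3))
        smi = _assemble_smiles(chain, n_rings, n_hal)
        smiles[lig] = smi
        n_arom = smi.count("c")
        # token count: chain C's + 'Cl' + '(' ')' + ring atoms/digits
        n_tokens = chain + 3 * n_hal + 8 * n_rings
        arom[i] = n_arom / n_tokens
    universe.smiles = smiles
    universe.aromatic_fraction = arom
    universe.dense_matrix.smiles = dict(smiles)
    universe.sparse_matrix.smiles = dict(smiles)
    return universe


def _assemble_smiles(chain: int, n_rings: int, n_halogens: int) -> str:
    parts = []
    for c in range(chain):
        parts.append("C")
        if n_halogens > 0 and c < n_halogens:
            parts.append("(Cl)")
    for _ in range(n_rings):
        parts.append("c1ccccc1")
    return "".join(parts)


def sparsify(
    dense: AffinityMatrix,
    missing_rate: float,
    coverage_bias: float = 0.0,
    seed: int = 0,
) -> AffinityMatrix:
    """Drop cells to emulate a sparse experimental panel.

    Cells vanish independently; ``coverage_bias`` > 0 tilts retention toward
    high-affinity cells (publication bias: strong binders get measured).
    Drop probabilities are rescaled so the expected overall missingness
    equals ``missing_rate``.  Observed cells keep their dense values.
    """
    if not 0 <= missing_rate < 1:
        raise SimulationError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    values = dense.values.copy()
    if missing_rate > 0:
        z = (values - np.nanmean(values)) / (np.nanstd(values) + 1e-12)
        p_drop = missing_rate * np.exp(-coverage_bias * z)
        scale = missing_rate / p_drop.mean()
        p_drop = np.clip(p_drop * scale, 0.0, 1.0)
        values[rng.random(values.shape) < p_drop] = np.nan
    return AffinityMatrix(
        list(dense.ligand_ids),
        list(dense.protein_ids),
        values,
        dict(dense.smiles),
        provenance="experimental",
    )
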