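import numpy as np
import pytest

from tasselect import AffinityRecord


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_records(rng, n_ligands=10, n_proteins=8, n_records=40, provenance="experimental"):
    """Random long-format records, duplicates allowed."""
    out = []
    for _ in range(n_records):
        i = int(rng.integers(n_ligands))
        j = int(rng.integers(n_proteins))
        out.append(
            AffinityRecord(
                ligand_id=f"L{i}",
                smiles=f"{'C' * (i + 1)}",
                protein_id=f"P{j}",
                pki=float(rng.uniform(4, 10)),
                pic50=float(rng.uniform(4, 10)) if rng.random() > 0.3 else None,
                provenance=provenance,
            )
        )
    return out
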