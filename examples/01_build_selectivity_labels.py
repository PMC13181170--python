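"""Build selectivity labels from an affinity table.

Generates a small synthetic ligand x protein panel, counts per-ligand
binding events above each affinity threshold, prunes thresholds that are
almost all zeros, binarizes against the column means and derives sample
weights.
"""

import numpy as np

from tasselect import build_training_table, count_bindings, generate_universe
from tasselect.simulate import UniverseParams

universe = generate_universe(UniverseParams(n_ligands=500, n_proteins=80, seed=0))
counts = count_bindings(universe.dense_matrix)
labels = build_training_table(universe.dense_matrix)

print("thresholds retained:", labels.retained_thresholds.thresholds)
print("binarization column means:", np.round(labels.column_means, 1))
print("fraction nonselective (label 0) per threshold:",
      np.round(labels.class_fractions, 3))
print("sample weights: mean %.6f, std %.2f, max/min ratio %.1f"
      % (labels.weights.mean(), labels.weights.std(),
         labels.weights.max() / labels.weights.min()))

# The column mean is the promiscuity cutoff: a ligand binding more proteins
# than average at a threshold is labeled 0 (nonselective) there; weights
# emphasize ligands with rare selectivity profiles and average to 1.
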