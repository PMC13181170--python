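"""Classifier diagnostics: confusion metrics, ROC/AUC, F1 curve.

Uses simulated scores around binary labels to show the metric surface,
including the two balanced-accuracy variants and the F1-optimal decision
threshold.
"""

import numpy as np

from tasselect.metrics import (
    balanced_accuracy_pr,
    balanced_accuracy_standard,
    confusion,
    precision_recall_f1,
    roc_curve_auc,
)
from tasselect.scoring import optimal_decision_threshold

rng = np.random.default_rng(0)
labels = (rng.random(2000) < 0.2).astype(int)  # imbalanced, 20% positive
scores = np.clip(0.55 * labels + rng.normal(0.25, 0.18, 2000), 0, 1)

threshold, best_f1 = optimal_decision_threshold(scores, labels)
calls = (scores >= threshold).astype(int)
c = confusion(labels, calls)
precision, recall, f1 = precision_recall_f1(c)
_, _, auc = roc_curve_auc(labels, scores)

print(f"F1-optimal decision threshold: {threshold:.2f} (F1 = {best_f1:.3f})")
print(f"confusion at that threshold: tp={c.tp} fp={c.fp} tn={c.tn} fn={c.fn}")
print(f"precision {precision:.3f}  recall {recall:.3f}  ROC-AUC {auc:.3f}")
print(f"balanced accuracy, precision/recall mean: {balanced_accuracy_pr(c):.3f}")
print(f"balanced accuracy, TPR/TNR mean:          {balanced_accuracy_standard(c):.3f}")

# Under class imbalance the two balanced-accuracy variants diverge; both
# are exposed under distinct names so reports are unambiguous.
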