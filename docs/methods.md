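# Methods

## Scope and data model

`tasselect` treats ligand–protein affinity as a single number per pair: the
combined affinity (pKi + pIC50)/2 on the −log10 molar scale. The two
quantities have different physical meaning but are numerically close, and
every downstream step only compares the value against thresholds, so the
average is a pragmatic working scalar rather than a physical claim. When a
record carries only one of the two, that value is used as-is by default;
strict both-required mode is available (`require_both`). This single-value
fallback matters for sparse experimental sources, where discarding
one-value records would bias the experimental selectivity estimator toward
well-characterized chemistry.

Duplicate (ligand, protein) measurements are kept at load time and resolved
at matrix construction (mean by default; max or hard error selectable).
Ligand and protein orderings are lexicographic, so matrix construction is
permutation-invariant and byte-reproducible.

## Label construction

For thresholds τ ∈ {7.0, 7.5, 8.0, 8.5, 9.0} (configurable, strictly
increasing):

- **Counts.** *n*<sub>*i*,τ</sub> = number of *observed* cells in row *i*
  strictly greater than τ. Exceedance is strict everywhere in the package;
  missing cells never count.
- **Pruning.** A threshold whose count column is ≥ `zero_fraction_cutoff`
  (default 0.95) zeros is dropped: a column that is almost all zeros
  cannot support a trainable binary task. On large public affinity panels
  the 9.0 threshold typically dies here.
- **Binarization.** *s*<sub>*i*,τ</sub> = 1 iff *n*<sub>*i*,τ</sub> ≤
  column mean. The tie goes to the selective class: a ligand at exactly
  average promiscuity is not flagged promiscuous. Ties are common because
  low-threshold column means are small integers. Column means are computed
  on the full ligand set before any train/test split.
- **Weights.** Within each label column, a ligand receives the inverse
  empirical frequency of its own label value, rescaled to unit column
  mean (1/(2f) has unit mean over a column with class frequency f). The
  per-column weights are averaged across columns and the final vector
  renormalized to mean exactly 1 (within 1e-9 by construction, asserted in
  tests). A single-class column is uninformative; it contributes weight 1
  with a warning. This inverse-frequency reading keeps every weight finite
  and strictly positive — normalizing raw counts instead would assign zero
  weight to fully selective ligands, contradicting the intent of
  emphasizing rare profiles.

The train/test split is a seeded ligand-level holdout (default 5 %); no
scaffold or protein-aware splitting is attempted.

## Sequence model

The classifier is a standard transformer encoder over SMILES tokens:

- **Tokenizer.** Deterministic regex segmentation: bracket atoms are single
  tokens, two-letter elements (Cl, Br, Si, Se, …), `%nn` ring closures,
  ring digits, bond and stereo symbols. Unknown characters map to a
  reserved `<unk>` token with a warning; sequences above 512 tokens are
  rejected naming the ligand. The vocabulary is built from the training
  corpus and frozen in the model artifact.
- **Architecture.** Trainable token embedding plus fixed sinusoidal
  positions → `n_layers` encoder blocks (multi-head self-attention with
  key-padding masks, post-norm residuals, ReLU feed-forward) → per-dimension
  maximum over sequence positions (padding excluded from the maxima) → one
  affine layer → logistic output per retained threshold. A frozen external
  encoder producing per-molecule vectors can be substituted; its vectors
  are memoized in a content-addressed cache keyed by SMILES, since a
  nontrainable encoder's outputs never change across epochs.
- **Training.** K-fold cross-validation (default K = 4): submodel *k*
  trains on all folds except *k* and validates on fold *k*; folds are a
  seeded permutation cut into contiguous blocks, stored in the artifact.
  The loss is sample-weighted binary cross-entropy summed over heads
  (weights renormalized to mean 1 at load, so uniform rescaling is a
  no-op). Optimizer is RAdam (lr 0.003); early stopping monitors
  validation loss with patience 10 by default, and the best-validation
  checkpoint per fold is kept. Inference averages the K submodels, so the
  ensemble score is always bounded by the submodel extremes.
- **Implementation.** The network runs on an internal numpy reverse-mode
  autodiff tape (`tasselect.autodiff`). Gradients of every operator and of
  the full model are checked against central finite differences in the
  test suite. Training is single-threaded and bit-reproducible under a
  fixed (data, config, seed) triple.

Two named configurations exist: the desk-scale default (2 layers, width
64, 4 heads) that trains in minutes on one CPU core, and `FULL_SCALE`
(6 layers, width 512, batch 128) for full-size runs. No test requires the
large configuration.

## TAS aggregation

TAS is the arithmetic mean of the per-threshold scores; a weighted mean is
available for users who want to emphasize particular affinity regimes. By
default the continuous head scores are averaged; a binarize-then-average
mode reproduces the training-label semantics. Binary calls use per-head
decision thresholds with ties called positive; the defaults for the
7.0/7.5/8.0/8.5 heads are the F1-optimal values 0.36/0.35/0.27/0.33, and
0.5 for any other head. The F1-optimal threshold search is an exhaustive
grid (step 0.01, smallest maximizer on ties). Calibration tables use
equal-width bins over [0, 1], reporting empty bins with an explicit
undefined marker.

## Selectivity estimators and the correlation harness

Three per-ligand estimates are compared:

- **model_tas** — ensemble scores (already oriented: high = selective);
- **cross_prediction** — fraction of a dense predicted matrix strictly
  above τ, denominator = all proteins;
- **experimental** — same fraction over measured cells only, restricted to
  ligands with ≥ 10 distinct-protein measurements (boundary inclusive).
  The protein universe is whatever survives that filter.

Exceed-fractions grow with promiscuity, so for cross-method comparison
they are re-oriented as 1 − fraction by default; the orientation mode is
recorded in the report. Spearman's ρ (average ranks for ties,
pairwise-complete over NaNs, NaN marker under zero variance or n < 3) is
computed per threshold and for the threshold-agnostic column means, on the
ligand intersection of the supplied frames, with n recorded. On a fully
observed matrix the experimental and cross-prediction estimators coincide
ligand-by-ligand, which the suite asserts exactly.

## Evaluation metrics

Positive class = selective = 1. Precision, recall and F1 come from the
confusion counts; 0/0 denominators yield an explicit `None` marker, and F1
with undefined components is reported as 0 (flagged) so grid searches stay
total. Two balanced accuracies are exposed under distinct names:
`balanced_accuracy_pr` = (precision + recall)/2, a nonstandard variant
in circulation, and the textbook `balanced_accuracy_standard` =
(TPR + TNR)/2; they differ under imbalance and silently conflating them is
a real reporting hazard. ROC points are taken at every distinct score
threshold with trapezoidal AUC (verified against O(n²) tie-corrected pair
counting); the F1 curve is evaluated on the same 0.01 grid as the
threshold search, so its maximum matches the search result by
construction.

## Synthetic universes

The generator emulates the two regimes the pipeline consumes — a dense
"predicted" panel and a sparse, biased "experimental" subset — with known
ground truth:

- Ligand promiscuity π ~ two-component Beta mixture, 85 %
  selective-rich Beta(2, 5) / 15 % promiscuous-rich Beta(6, 2).
- Affinity a = μ + α·logit(π) + β·d + ε with protein druggability
  d ~ N(0, 1), noise ε ~ N(0, σ²), clipped to [3, 12] so values straddle
  the 7.0–8.5 working thresholds.
- Defaults μ = 7.0, α = 0.9, β = 1.2, σ = 0.4. These were chosen once so
  that (i) per-threshold binding counts rank-recover π at Spearman ≥ 0.9
  with margin across seeds, (ii) the nonselective class is a minority
  that shrinks with threshold (≈ 0.40/0.36/0.31/0.26/0.21 across
  7.0–9.0), and (iii) the four working thresholds all survive pruning.
  Real proteome-wide panels are substantially more zero-inflated at high
  thresholds than this default; that regime destroys rank information by
  construction (massive ties at count 0), so it is exercised by dedicated
  pruning and imbalance tests on constructed tables rather than by the
  default universe.
- SMILES come from a fragment grammar: the promiscuity decile sets the
  number of benzene rings (decile // 3) and halogen branches
  (decile // 4) on an alkyl chain that shrinks with the decile, so the
  aromatic-token fraction is monotone in π (Spearman ≥ 0.8 asserted).
  The bottom decile is a plain chain. Strings are syntactically valid,
  tokenize without unknown tokens, and parse under RDKit when present.
- Sparsification drops cells independently; `coverage_bias` > 0 tilts
  retention toward high-affinity cells (publication bias), with drop
  probabilities rescaled so overall missingness matches `missing_rate`
  in expectation.

What passing tests on this universe do and do not show: they demonstrate
that the full pipeline — label construction, weighting, training,
TAS aggregation, estimator comparison — recovers a planted monotone
composition→promiscuity signal end to end. They do not demonstrate
chemistry-level generalization: real SMILES carry far richer and far
noisier structure–promiscuity relations than the fragment grammar, and
real experimental coverage is more biased than the independent-drop model.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale by choice: oracle
equivalence on random fixtures up to 100 × 50, estimator consistency at
1,000 ligands × 100 proteins, and pipeline recovery with a 4-fold,
2-layer, width-64 ensemble on a 5,000-ligand universe (seed 1,
6 epochs, batch 128), which reaches per-head held-out ROC-AUC ≥ 0.8 and
Spearman(TAS, 1 − π) ≥ 0.5. Attention logits use an additive −1e9 padding
mask; max pooling routes gradients to the first attaining position;
validation loss clips probabilities at 1e-12 for the log. All randomness
flows through explicit `numpy.random.default_rng` seeds; there is no
global random state.

## Known limitations

- The trainable token embedding replaces a large pretrained molecular
  encoder; the external-embedding hook accepts per-molecule vectors only
  (entered as a single-position sequence), not per-token ones.
- TAS conflates "selective" with "weakly binding everywhere": a high score
  means few predicted binding events above threshold, not potency at a
  chosen target. It is a pre-filter, to be paired with a target-specific
  affinity model.
- The correlation harness reports rank agreement only; no significance
  testing or confidence intervals.
- Training is pure numpy on one core: fine at 10³–10⁵ ligands with the
  desk-scale configuration, not intended for million-ligand corpora.
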