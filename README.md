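# tasselect

Target-agnostic selectivity (TAS) estimation for small molecules: a toolkit
for predicting a ligand's proteome-wide binding propensity directly from its
SMILES string, with no reference target protein.

## The problem

Off-target binding is a major driver of drug attrition. In principle a
drug–target affinity (DTA) model can profile a candidate against thousands of
proteins and count the predicted off-targets, but at library scale that
cross-prediction campaign is computationally prohibitive. `tasselect`
implements the alternative: distill proteome-wide affinity information into
per-ligand *selectivity labels*, train a lightweight sequence classifier on
SMILES alone, and summarize its outputs as a single score usable as a fast
promiscuity pre-filter in virtual screening and de novo design.

## The method

Given a ligand × protein table of combined affinities
(pKi + pIC50)/2 on the −log10 molar scale:

1. **Binding counts.** For each ligand *i* and affinity threshold
   τ ∈ {7.0, 7.5, 8.0, 8.5, 9.0}, count the proteins with affinity
   strictly above τ: *n*<sub>*i*,τ</sub>. Thresholds whose count column is
   ≥ 95 % zeros are pruned as untrainable.
2. **Labels.** Binarize against the column mean:
   *s*<sub>*i*,τ</sub> = 1 (selective) iff
   *n*<sub>*i*,τ</sub> ≤ mean<sub>τ</sub>, else 0 (promiscuous).
3. **Sample weights.** Per column, inverse class frequency scaled to unit
   column mean; averaged across columns and renormalized so the final
   weight vector has mean exactly 1. Rare selectivity profiles weigh more.
4. **Model.** A transformer-style encoder over SMILES tokens (embedding →
   self-attention stack → per-dimension max pooling → one logistic head per
   threshold), trained as a K-fold cross-validation ensemble with
   sample-weighted binary cross-entropy, RAdam, and early stopping on
   validation loss. Inference averages the submodels.
5. **TAS.** The target-agnostic selectivity score is the mean of the
   per-threshold scores (optionally weighted, optionally binarized first
   with per-head decision thresholds 0.36/0.35/0.27/0.33 for
   7.0/7.5/8.0/8.5). High TAS ⇒ predicted to bind few proteins at any
   pharmacologically relevant affinity.
6. **Benchmarking.** A Spearman harness compares three estimator families
   per threshold and threshold-agnostically: the model's scores, the
   exceed-fraction over a dense predicted matrix (cross-prediction), and
   the exceed-fraction over measured affinities for ligands with ≥ 10
   distinct-protein measurements (experimental).

The neural network is implemented in numpy with an internal reverse-mode
autodiff tape (gradient-checked against central differences in the test
suite), so the package has no deep-learning framework dependency.

## Worked example

`examples/02_train_and_score.py` trains a small 2-fold ensemble on a
synthetic universe with known ground-truth promiscuity π and scores the
held-out ligands:

```
scored 120 held-out ligands at thresholds (7.0, 7.5, 8.0, 8.5, 9.0)
   CCCCCCCCC                    head scores [0.53 0.52 0.57 0.61 0.65] TAS 0.58 (true selectivity 0.71)
   C(Cl)C(Cl)c1ccccc1c1ccccc1c1 head scores [0.39 0.45 0.5  0.54 0.6 ] TAS 0.49 (true selectivity 0.07)
Spearman(TAS, ground-truth selectivity): 0.866
```

Each head score is the ensemble's probability that the ligand is selective
at that affinity threshold; TAS is their mean. The plain alkyl chain (a
selective ligand in the synthetic grammar) scores above the halogenated
polyaromatic (promiscuous), and across the test set the TAS ranking
recovers the latent selectivity with Spearman ρ = 0.87 — at this deliberately
small model and sample size. The other examples cover label construction,
the estimator correlation harness, and classifier diagnostics.

A CLI mirrors the library for shell pipelines:

```bash
tasselect simulate --out-dir data --n-ligands 1000 --seed 0
tasselect build-labels data/dense_predicted.csv --out-csv data/train.csv
tasselect train data/train.csv --model-dir model
tasselect predict model my_ligands.smi --out-csv scores.csv
tasselect correlate data/dense_predicted.csv data/sparse_experimental.csv --out-dir corr
```

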