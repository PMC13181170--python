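"""Multi-head selectivity classifier over SMILES tokens.

Architecture: token embedding (+ fixed sinusoidal positions) -> a stack of
self-attention encoder layers with ReLU feed-forward blocks -> per-dimension
maximum pooling over sequence positions -> a single affine layer mapping to
one logistic output per affinity threshold.  Training is K-fold
cross-validation: submodel k trains on all folds but k, validates on fold k,
with sample-weighted binary cross-entropy summed over heads, RAdam, and
early stopping on validation loss.  Inference averages the submodels.

The ligand encoder is a trainable embedding table by default; a frozen
external encoder producing per-molecule vectors can be plugged in instead
(vectors enter the same encoder stack as a single-position sequence).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import autodiff as ad
from .tokenizer import (
    MAX_TOKENS,
    TokenizationError,
    TokenSequence,
    Vocabulary,
    tokenize_smiles,
)

logger = logging.getLogger(__name__)


class ModelError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one submodel and of the ensemble.

    The default is a desk-scale configuration (2 layers, width 64) that
    trains in minutes on a CPU; :data:`FULL_SCALE` holds the full-size
    variant (6 layers, width 512, batch 128).
    """

    n_layers: int = 2
    model_dim: int = 64
    n_heads: int = 4
    ffn_dim: int | None = None  # defaults to 4 * model_dim
    n_outputs: int = 4
    learning_rate: float = 0.003
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 10
    k_folds: int = 4
    seed: int = 0
    max_tokens: int = MAX_TOKENS
    encoder_mode: str = "trainable_embedding"  # or "external_embedding"

    def __post_init__(self) -> None:
        for name in (
            "n_layers", "model_dim", "n_heads", "n_outputs", "batch_size",
            "max_epochs", "patience", "k_folds", "max_tokens",
        ):
            if getattr(self, name) <= 0:
                raise ModelError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ModelError("learning_rate must be positive")
        if self.model_dim % self.n_heads:
            raise ModelError("model_dim must be divisible by n_heads")
        if self.k_folds < 2:
            raise ModelError("cross-validation requires k_folds >= 2")

    @property
    def ffn(self) -> int:
        return self.ffn_dim or 4 * self.model_dim


FULL_SCALE = ModelConfig(
    n_layers=6, model_dim=512, n_heads=8, batch_size=128, learning_rate=0.003
)


def sinusoidal_positions(n_pos: int, dim: int) -> np.ndarray:
    pos = np.arange(n_pos)[:, None]
    i = np.arange(dim)[None, :]
    angles = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angles), np.cos(angles))
    return enc


class SequenceClassifier:
    """One submodel: encoder stack + max pooling + logistic heads."""

    def __init__(self, config: ModelConfig, vocab_size: int, seed: int) -> None:
        self.config = config
        self.vocab_size = vocab_size
        rng = np.random.default_rng(seed)
        d, f, h = config.model_dim, config.ffn, config.n_outputs
        std = 0.02

        def w(*shape: int) -> ad.Tensor:
            return ad.parameter(rng.normal(0.0, std, shape))

        p: dict[str, ad.Tensor] = {"emb": w(vocab_size, d)}
        for l in range(config.n_layers):
            p[f"l{l}.wq"] = w(d, d)
            p[f"l{l}.wk"] = w(d, d)
            p[f"l{l}.wv"] = w(d, d)
            p[f"l{l}.wo"] = w(d, d)
            p[f"l{l}.ln1g"] = ad.parameter(np.ones(d))
            p[f"l{l}.ln1b"] = ad.parameter(np.zeros(d))
            p[f"l{l}.w1"] = w(d, f)
            p[f"l{l}.b1"] = ad.parameter(np.zeros(f))
            p[f"l{l}.w2"] = w(f, d)
            p[f"l{l}.b2"] = ad.parameter(np.zeros(d))
            p[f"l{l}.ln2g"] = ad.parameter(np.ones(d))
            p[f"l{l}.ln2b"] = ad.parameter(np.zeros(d))
        p["head.w"] = w(d, h)
        p["head.b"] = ad.parameter(np.zeros(h))
        self.params = p
        self.positions = sinusoidal_positions(config.max_tokens, d)

    def encode(self, ids: np.ndarray, pad_id: int) -> ad.Tensor:
        """ids (B, L) -> pooled representation (B, D)."""
        cfg = self.config
        valid = ids != pad_id
        if not valid.any(axis=1).all():
            raise ModelError("batch contains an all-padding sequence")
        B, L = ids.shape
        d, nh = cfg.model_dim, cfg.n_heads
        dh = d // nh

        x = ad.add(
            ad.embedding(self.params["emb"], ids),
            ad.constant(self.positions[None, :L, :]),
        )
        # additive key-padding mask for attention logits, (B, 1, 1, L)
        att_mask = np.where(valid, 0.0, -1e9)[:, None, None, :]
        for l in range(cfg.n_layers):
            x = self._attention_block(x, l, att_mask, B, L, d, nh, dh)
            x = self._ffn_block(x, l)
        return ad.masked_max_over_axis1(x, valid)

    def _attention_block(self, x, l, att_mask, B, L, d, nh, dh):
        p = self.params

        def split(t: ad.Tensor) -> ad.Tensor:  # (B,L,D) -> (B,nh,L,dh)
            return ad.transpose(ad.reshape(t, (B, L, nh, dh)), (0, 2, 1, 3))

        q = split(ad.matmul(x, p[f"l{l}.wq"]))
        k = split(ad.matmul(x, p[f"l{l}.wk"]))
        v = split(ad.matmul(x, p[f"l{l}.wv"]))
        scores = ad.scale(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))), dh**-0.5)
        att = ad.softmax_lastaxis(scores, att_mask)
        ctx = ad.reshape(ad.transpose(ad.matmul(att, v), (0, 2, 1, 3)), (B, L, d))
        out = ad.matmul(ctx, p[f"l{l}.wo"])
        return ad.layer_norm(ad.add(x, out), p[f"l{l}.ln1g"], p[f"l{l}.ln1b"])

    def _ffn_block(self, x, l):
        p = self.params
        h = ad.relu(ad.add(ad.matmul(x, p[f"l{l}.w1"]), p[f"l{l}.b1"]))
        out = ad.add(ad.matmul(h, p[f"l{l}.w2"]), p[f"l{l}.b2"])
        return ad.layer_norm(ad.add(x, out), p[f"l{l}.ln2g"], p[f"l{l}.ln2b"])

    def logits(self, ids: np.ndarray, pad_id: int) -> ad.Tensor:
        pooled = self.encode(ids, pad_id)
        return ad.add(ad.matmul(pooled, self.params["head.w"]), self.params["head.b"])

    def forward(self, ids: np.ndarray, pad_id: int) -> np.ndarray:
        """Scores in (0, 1), shape (B, n_outputs).  No gradient tape kept."""
        return ad.sigmoid(self.logits(ids, pad_id).data)

    def state(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = np.array(state[k], dtype=np.float64)


def _pad_batch(seqs: list[list[int]], pad_id: int) -> np.ndarray:
    L = max(len(s) for s in seqs)
    out = np.full((len(seqs), L), pad_id, dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s
    return out


@dataclass
class EnsembleModel:
    """K cross-validation submodels with averaged inference."""

    submodels: list[SequenceClassifier]
    config: ModelConfig
    vocabulary: Vocabulary
    fold_assignment: np.ndarray  # per-training-ligand fold index
    training_history: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["fold", "epoch", "train_loss", "val_loss"]
        )
    )

    def predict_scores(
        self, smiles: Sequence[str]
    ) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
        """Average submodel scores per threshold head.

        Returns (scores, failures); failures lists (position, reason) for
        SMILES that could not be tokenized or exceed the length budget —
        the remaining ligands are still scored.
        """
        encoded: list[list[int]] = []
        ok_pos: list[int] = []
        failures: list[tuple[int, str]] = []
        for i, smi in enumerate(smiles):
            try:
                seq = tokenize_smiles(smi, self.config.max_tokens)
                encoded.append(self.vocabulary.encode(seq))
                ok_pos.append(i)
            except TokenizationError as exc:
                failures.append((i, str(exc)))
        n_heads = self.config.n_outputs
        scores = np.full((len(smiles), n_heads), np.nan)
        pad = self.vocabulary.pad_id
        bs = self.config.batch_size
        for start in range(0, len(encoded), bs):
            chunk = encoded[start : start + bs]
            ids = _pad_batch(chunk, pad)
            acc = np.zeros((len(chunk), n_heads))
            for sm in self.submodels:
                acc += sm.forward(ids, pad)
            rows = ok_pos[start : start + bs]
            scores[rows] = acc / len(self.submodels)
        df = pd.DataFrame(scores, columns=[f"head_{k}" for k in range(n_heads)])
        return df, failures

    def save(self, directory: str | Path, head_names: list[str] | None = None) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        cfg["head_names"] = head_names or [
            f"head_{k}" for k in range(self.config.n_outputs)
        ]
        (directory / "config.json").write_text(json.dumps(cfg, indent=2))
        (directory / "vocabulary.json").write_text(
            json.dumps(self.vocabulary.tokens())
        )
        np.savetxt(
            directory / "fold_assignment.csv", self.fold_assignment, fmt="%d"
        )
        self.training_history.to_csv(directory / "history.csv", index=False)
        for k, sm in enumerate(self.submodels):
            np.savez(directory / f"params_fold{k}.npz", **sm.state())

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleModel":
        directory = Path(directory)
        cfg_raw = json.loads((directory / "config.json").read_text())
        cfg_raw.pop("head_names", None)
        config = ModelConfig(**cfg_raw)
        vocab = Vocabulary(json.loads((directory / "vocabulary.json").read_text()))
        folds = np.loadtxt(directory / "fold_assignment.csv", dtype=int, ndmin=1)
        history = pd.read_csv(directory / "history.csv")
        submodels = []
        for k in range(config.k_folds):
            sm = SequenceClassifier(config, len(vocab), seed=0)
            with np.load(directory / f"params_fold{k}.npz") as npz:
                sm.load_state(dict(npz))
            submodels.append(sm)
        return cls(submodels, config, vocab, folds, history)

    @staticmethod
    def head_names_of(directory: str | Path) -> list[str]:
        cfg = json.loads((Path(directory) / "config.json").read_text())
        return cfg.get("head_names", [])


def assign_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded permutation cut into k contiguous blocks -> fold index per row."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    bounds = np.linspace(0, n, k + 1).astype(int)
    for f in range(k):
        folds[perm[bounds[f] : bounds[f + 1]]] = f
    return folds


def train_ensemble(
    table: pd.DataFrame,
    config: ModelConfig | None = None,
    *,
    label_cols: list[str] | None = None,
    progress: Callable[[str], None] | None = None,
) -> EnsembleModel:
    """Train the K-fold ensemble from a training table.

    ``table`` must carry ``smiles``, binary label columns (``sel_*`` by
    default) and a ``weight`` column.  Weights are renormalized to mean 1 at
    load, so uniformly rescaling them does not change the optimization.
    """
    config = config or ModelConfig()
    label_cols = label_cols or [c for c in table.columns if c.startswith("sel_")]
    if not label_cols:
        raise ModelError("no label columns found (expected sel_* columns)")
    if "smiles" not in table.columns or "weight" not in table.columns:
        raise ModelError("training table needs 'smiles' and 'weight' columns")
    if len(label_cols) != config.n_outputs:
        config = replace(config, n_outputs=len(label_cols))

    smiles = table["smiles"].tolist()
    labels = table[label_cols].to_numpy(dtype=float)
    weights = table["weight"].to_numpy(dtype=float)
    weights = weights / weights.mean()

    seqs = [tokenize_smiles(s, config.max_tokens) for s in smiles]
    vocab = Vocabulary.from_corpus(seqs)
    encoded = [vocab.encode(s) for s in seqs]
    n = len(encoded)
    if n < max(config.k_folds * 2, config.batch_size):
        raise ModelError(
            f"{n} rows is too few for {config.k_folds}-fold cross-validation "
            f"at batch size {config.batch_size}"
        )
    folds = assign_folds(n, config.k_folds, config.seed)

    for j, col in enumerate(label_cols):
        if len(np.unique(labels[:, j])) < 2:
            logger.warning("label column %s is single-class; head still trained", col)

    submodels: list[SequenceClassifier] = []
    history_rows: list[dict] = []
    for k in range(config.k_folds):
        sm, rows = _train_fold(
            config, vocab, encoded, labels, weights, folds, k, progress
        )
        submodels.append(sm)
        history_rows.extend(rows)
    history = pd.DataFrame(history_rows)
    return EnsembleModel(submodels, config, vocab, folds, history)


def _train_fold(config, vocab, encoded, labels, weights, folds, k, progress):
    train_idx = np.flatnonzero(folds != k)
    val_idx = np.flatnonzero(folds == k)
    sm = SequenceClassifier(config, len(vocab), seed=config.seed * 1009 + k)
    opt = ad.RAdam(sm.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed * 7919 + k)
    pad = vocab.pad_id
    best_val = np.inf
    best_state = sm.state()
    best_epoch = 0
    rows = []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(train_idx)
        tot, cnt = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            ids = _pad_batch([encoded[i] for i in idx], pad)
            opt.zero_grad()
            loss = ad.weighted_bce_with_logits(
                sm.logits(ids, pad), labels[idx], weights[idx]
            )
            if not np.isfinite(loss.data):
                raise ModelError(
                    f"non-finite training loss at fold {k}, epoch {epoch}"
                )
            loss.backward()
            opt.step()
            tot += float(loss.data) * len(idx)
            cnt += len(idx)
        val = _eval_loss(sm, encoded, labels, weights, val_idx, pad, config)
        rows.append(
            {"fold": k, "epoch": epoch, "train_loss": tot / cnt, "val_loss": val}
        )
        if progress:
            progress(f"fold {k} epoch {epoch}: train {tot/cnt:.4f} val {val:.4f}")
        if val < best_val - 1e-6:
            best_val, best_state, best_epoch = val, sm.state(), epoch
        elif epoch - best_epoch >= config.patience:
            break
    sm.load_state(best_state)
    return sm, rows


def _eval_loss(sm, encoded, labels, weights, idx, pad, config):
    tot, cnt = 0.0, 0
    for start in range(0, len(idx), config.batch_size):
        b = idx[start : start + config.batch_size]
        ids = _pad_batch([encoded[i] for i in b], pad)
        z = sm.forward(ids, pad)
        z = np.clip(z, 1e-12, 1 - 1e-12)
        per = -(labels[b] * np.log(z) + (1 - labels[b]) * np.log(1 - z))
        tot += float((per.sum(axis=1) * weights[b]).sum())
        cnt += len(b)
    return tot / cnt
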