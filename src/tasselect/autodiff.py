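"""Minimal reverse-mode automatic differentiation over numpy arrays.

Define-by-run tape, just enough surface for a small transformer encoder:
matmul (batched), broadcast add/mul, relu, softmax, layer norm, embedding
lookup, masked max over an axis, and a fused sigmoid-BCE loss.  Gradients
are checked against central differences in the test suite.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(
        self,
        data: np.ndarray,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents
        )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topological sort: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


def constant(data: np.ndarray) -> Tensor:
    return Tensor(data)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.shape))

    return Tensor(out_data, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, (a, b), bwd)


def scale(a: Tensor, s: float) -> Tensor:
    def bwd(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g * s)

    return Tensor(a.data * s, (a,), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product; leading axes broadcast as in numpy."""
    out_data = a.data @ b.data

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a.accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b.accumulate(_unbroadcast(gb, b.shape))

    return Tensor(out_data, (a, b), bwd)


def sum_all(a: Tensor) -> Tensor:
    def bwd(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(np.broadcast_to(g, a.shape).copy())

    return Tensor(np.array(a.data.sum()), (a,), bwd)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g * mask)

    return Tensor(a.data * mask, (a,), bwd)


def softmax_lastaxis(a: Tensor, additive_mask: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis; ``additive_mask`` (e.g. -1e9 at padding)
    is applied to the logits before normalization."""
    z = a.data if additive_mask is None else a.data + additive_mask
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad:
            dot = (g * s).sum(axis=-1, keepdims=True)
            a.accumulate((g - dot) * s)

    return Tensor(s, (a,), bwd)


def layer_norm(a: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with learned gain and bias."""
    mu = a.data.mean(axis=-1, keepdims=True)
    xc = a.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gain.data + bias.data
    d = a.data.shape[-1]

    def bwd(g: np.ndarray) -> None:
        if gain.requires_grad:
            gain.accumulate(_unbroadcast(g * xhat, gain.shape))
        if bias.requires_grad:
            bias.accumulate(_unbroadcast(g, bias.shape))
        if a.requires_grad:
            gx = g * gain.data
            ga = inv * (
                gx
                - gx.mean(axis=-1, keepdims=True)
                - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            )
            a.accumulate(ga)
        _ = d

    return Tensor(out_data, (a, gain, bias), bwd)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup: ids (B, L) of int -> (B, L, D)."""
    ids = np.asarray(ids)
    out_data = table.data[ids]

    def bwd(g: np.ndarray) -> None:
        if table.requires_grad:
            gt = np.zeros_like(table.data)
            np.add.at(gt, ids.reshape(-1), g.reshape(-1, g.shape[-1]))
            table.accumulate(gt)

    return Tensor(out_data, (table,), bwd)


def masked_max_over_axis1(a: Tensor, valid_mask: np.ndarray) -> Tensor:
    """Per-dimension maximum over sequence positions (axis 1), ignoring
    positions where ``valid_mask`` (B, L) is False.  Gradient flows to the
    first attaining position."""
    masked = np.where(valid_mask[:, :, None], a.data, -np.inf)
    arg = masked.argmax(axis=1)  # (B, D)
    out_data = np.take_along_axis(masked, arg[:, None, :], axis=1)[:, 0, :]

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            b_idx = np.arange(a.data.shape[0])[:, None]
            d_idx = np.arange(a.data.shape[2])[None, :]
            ga[b_idx, arg, d_idx] = g
            a.accumulate(ga)

    return Tensor(out_data, (a,), bwd)


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    orig = a.shape

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g.reshape(orig))

    return Tensor(a.data.reshape(shape), (a,), bwd)


def transpose(a: Tensor, axes: tuple[int, ...]) -> Tensor:
    inv = np.argsort(axes)

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g.transpose(inv))

    return Tensor(a.data.transpose(axes), (a,), bwd)


def weighted_bce_with_logits(
    logits: Tensor, targets: np.ndarray, weights: np.ndarray
) -> Tensor:
    """Sample-weighted binary cross-entropy summed over output heads,
    averaged over the batch.  ``logits`` (B, H), ``targets`` (B, H) in {0,1},
    ``weights`` (B,)."""
    z = logits.data
    # stable softplus(z) - y*z
    per = np.maximum(z, 0) - targets * z + np.log1p(np.exp(-np.abs(z)))
    w = weights[:, None]
    out_data = np.array((per * w).sum(axis=1).mean())
    n = z.shape[0]

    def bwd(g: np.ndarray) -> None:
        if logits.requires_grad:
            p = 1.0 / (1.0 + np.exp(-z))
            logits.accumulate(g * w * (p - targets) / n)

    return Tensor(out_data, (logits,), bwd)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class RAdam:
    """Rectified Adam: variance-rectified adaptive learning rate.

    Falls back to an unadapted (momentum-only) step while the variance
    estimate is unreliable (rectification term <= 4).
    """

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 0.003,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = self.b1**self.t
        b2t = self.b2**self.t
        rho = self.rho_inf - 2.0 * self.t * b2t / (1.0 - b2t)
        if rho > 4.0:
            r = np.sqrt(
                ((rho - 4.0) * (rho - 2.0) * self.rho_inf)
                / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho)
            )
        else:
            r = None
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - b1t)
            if r is not None:
                vhat = np.sqrt(self.v[k] / (1 - b2t))
                p.data -= self.lr * r * mhat / (vhat + self.eps)
            else:
                p.data -= self.lr * mhat
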