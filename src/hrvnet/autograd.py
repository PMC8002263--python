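"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the tensor operations the 1-D UNet++ classifier needs:
broadcast arithmetic, matrix products, length-preserving 1-D convolution,
max-pooling, nearest-neighbour / zero-interleaved up-sampling, channel
concatenation, axis means and the two squashing nonlinearities.  Gradients
are accumulated by topologically-sorted backward passes, micrograd-style.

Feature maps follow the (batch, channels, length) layout throughout.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "add",
    "sub",
    "mul",
    "pow_",
    "matmul",
    "relu",
    "sigmoid",
    "conv1d",
    "maxpool1d",
    "upsample_nearest",
    "zero_interleave",
    "concat",
    "mean",
    "reshape",
]


class Tensor:
    """An array node in the computation graph.

    ``requires_grad`` marks trainable leaves; interior nodes inherit it from
    their parents.  ``backward()`` may only be called on a scalar.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray | float,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape))
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    # light operator sugar used by the layers
    def __add__(self, other: "Tensor") -> "Tensor":
        return add(self, other)

    def __sub__(self, other: "Tensor") -> "Tensor":
        return sub(self, other)

    def __mul__(self, other: "Tensor") -> "Tensor":
        return mul(self, other)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x: Tensor | float | np.ndarray) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _node(
    data: np.ndarray,
    parents: Sequence[Tensor],
    backward: Callable[[np.ndarray], None],
) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=parents if req else (),
                  backward=backward if req else None)


def add(a: Tensor, b: Tensor | float) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bwd(g: np.ndarray) -> None:
        a.accumulate(_unbroadcast(g, a.data.shape))
        b.accumulate(_unbroadcast(g, b.data.shape))

    return _node(a.data + b.data, (a, b), bwd)


def sub(a: Tensor, b: Tensor | float) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bwd(g: np.ndarray) -> None:
        a.accumulate(_unbroadcast(g, a.data.shape))
        b.accumulate(_unbroadcast(-g, b.data.shape))

    return _node(a.data - b.data, (a, b), bwd)


def mul(a: Tensor, b: Tensor | float) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def bwd(g: np.ndarray) -> None:
        a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(a.data * b.data, (a, b), bwd)


def pow_(a: Tensor, exponent: float) -> Tensor:
    a = _as_tensor(a)
    out = a.data ** exponent

    def bwd(g: np.ndarray) -> None:
        a.accumulate(g * exponent * a.data ** (exponent - 1.0))

    return _node(out, (a,), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product (batch, features) @ (features, out)."""

    def bwd(g: np.ndarray) -> None:
        a.accumulate(g @ b.data.T)
        b.accumulate(a.data.T @ g)

    return _node(a.data @ b.data, (a, b), bwd)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bwd(g: np.ndarray) -> None:
        a.accumulate(g * mask)

    return _node(np.where(mask, a.data, 0.0), (a,), bwd)


def sigmoid(a: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g: np.ndarray) -> None:
        a.accumulate(g * out * (1.0 - out))

    return _node(out, (a,), bwd)


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Length-preserving ('same') 1-D convolution, stride 1, odd kernel.

    ``x``: (B, C_in, L); ``w``: (C_out, C_in, K); ``b``: (C_out,).
    """
    K = w.data.shape[2]
    if K % 2 != 1:
        raise ValueError("conv1d requires an odd kernel width")
    p = (K - 1) // 2
    B, _, L = x.data.shape
    C_out = w.data.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p)))
    # shift-and-accumulate over kernel taps: each tap is one BLAS contraction
    out = np.empty((B, C_out, L))
    out[:] = b.data[None, :, None]
    for k in range(K):
        # (B, L, C_in) @ (C_in, C_out) -> (B, L, C_out)
        tap = np.tensordot(xp[:, :, k:k + L], w.data[:, :, k], axes=([1], [1]))
        out += tap.transpose(0, 2, 1)

    def bwd(g: np.ndarray) -> None:
        dw = np.empty_like(w.data)
        for k in range(K):
            dw[:, :, k] = np.tensordot(g, xp[:, :, k:k + L], axes=([0, 2], [0, 2]))
        w.accumulate(dw)
        b.accumulate(g.sum(axis=(0, 2)))
        dxp = np.zeros_like(xp)
        for k in range(K):
            tap = np.tensordot(g, w.data[:, :, k], axes=([1], [0]))  # (B, L, C_in)
            dxp[:, :, k:k + L] += tap.transpose(0, 2, 1)
        x.accumulate(dxp[:, :, p:p + L] if p else dxp)

    return _node(out, (x, w, b), bwd)


def maxpool1d(x: Tensor, kernel: int = 2, stride: int = 2, pad: int = 0) -> Tensor:
    """Windowed max over the length axis.

    With kernel=stride=2 this is the halving down-sampler; kernel=3, stride=1,
    pad=1 gives the length-preserving pooled branch of the inception block.
    """
    B, C, L = x.data.shape
    if pad == 0 and stride == kernel and L % kernel != 0:
        raise ValueError(f"length {L} not divisible by pooling stride {kernel}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)), constant_values=-np.inf)
    win = sliding_window_view(xp, kernel, axis=2)[:, :, ::stride]  # (B,C,Lo,k)
    idx = win.argmax(axis=3)
    out = np.take_along_axis(win, idx[..., None], axis=3)[..., 0]
    Lo = out.shape[2]

    def bwd(g: np.ndarray) -> None:
        gx = np.zeros((B, C, L + 2 * pad))
        bi, ci, li = np.meshgrid(
            np.arange(B), np.arange(C), np.arange(Lo), indexing="ij"
        )
        np.add.at(gx, (bi, ci, li * stride + idx), g)
        x.accumulate(gx[:, :, pad:pad + L] if pad else gx)

    return _node(out, (x,), bwd)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour repetition along the length axis."""
    out = np.repeat(x.data, factor, axis=2)

    def bwd(g: np.ndarray) -> None:
        B, C, L2 = g.shape
        x.accumulate(g.reshape(B, C, L2 // factor, factor).sum(axis=3))

    return _node(out, (x,), bwd)


def zero_interleave(x: Tensor, factor: int = 2) -> Tensor:
    """Insert ``factor - 1`` zeros after every sample (transposed-conv stuffing)."""
    B, C, L = x.data.shape
    out = np.zeros((B, C, L * factor))
    out[:, :, ::factor] = x.data

    def bwd(g: np.ndarray) -> None:
        x.accumulate(g[:, :, ::factor])

    return _node(out, (x,), bwd)


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    mu: np.ndarray,
    var: np.ndarray,
    eps: float,
    batch_stats: bool,
) -> Tensor:
    """Fused per-channel normalisation y = γ·(x − μ)/√(σ² + ε) + β.

    ``mu``/``var`` are (1, C, 1) statistics over the (batch, length) axes.
    With ``batch_stats`` they are functions of ``x`` (training mode) and the
    backward pass includes their dependence on ``x``; otherwise they are
    treated as constants (running averages, evaluation mode).
    """
    std = np.sqrt(var + eps)
    xhat = (x.data - mu) / std
    out = gamma.data * xhat + beta.data

    def bwd(g: np.ndarray) -> None:
        beta.accumulate(g.sum(axis=(0, 2), keepdims=True))
        gamma.accumulate((g * xhat).sum(axis=(0, 2), keepdims=True))
        dxhat = g * gamma.data
        if batch_stats:
            n = x.data.shape[0] * x.data.shape[2]
            s1 = dxhat.sum(axis=(0, 2), keepdims=True)
            s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
            x.accumulate((dxhat - s1 / n - xhat * (s2 / n)) / std)
        else:
            x.accumulate(dxhat / std)

    return _node(out, (x, gamma, beta), bwd)


def concat(xs: Iterable[Tensor], axis: int = 1) -> Tensor:
    xs = list(xs)
    sizes = [t.data.shape[axis] for t in xs]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: np.ndarray) -> None:
        for t, lo, hi in zip(xs, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t.accumulate(g[tuple(sl)])

    return _node(np.concatenate([t.data for t in xs], axis=axis), xs, bwd)


def mean(x: Tensor, axis: int | tuple[int, ...], keepdims: bool = False) -> Tensor:
    axes = (axis,) if isinstance(axis, int) else tuple(axis)
    n = int(np.prod([x.data.shape[a] for a in axes]))
    out = x.data.mean(axis=axes, keepdims=keepdims)

    def bwd(g: np.ndarray) -> None:
        gg = g if keepdims else np.expand_dims(g, axes)
        x.accumulate(np.broadcast_to(gg, x.data.shape) / n)

    return _node(out, (x,), bwd)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    old = x.data.shape

    def bwd(g: np.ndarray) -> None:
        x.accumulate(g.reshape(old))

    return _node(x.data.reshape(shape), (x,), bwd)
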