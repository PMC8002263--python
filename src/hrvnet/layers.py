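"""Trainable layers and the three convolution-block variants.

The block variants mirror the architecture study: a plain residual block
(Conv1D→BN→ReLU→Conv1D→BN with the additive shortcut taken from the first
convolution's output), the squeeze-and-excitation residual block that gates
the residual branch per channel before the shortcut addition, and an
inception block with parallel kernel widths {1, 3, 5} plus a pooled branch.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def set_training(self, training: bool) -> None:
        for m in self.modules():
            m.training = training

    training: bool = True


class Conv1d(Module):
    """Same-padded stride-1 convolution; He/variance-scaling weight init."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (c_in * kernel))
        self.weight = Tensor(rng.normal(0.0, std, (c_out, c_in, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv1d(x, self.weight, self.bias)


class BatchNorm1d(Module):
    """Per-channel batch normalisation over (batch, length).

    Training mode normalises with batch statistics and updates exponential
    running averages; evaluation mode uses the running averages, making the
    forward map deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, channels, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1))
        self.running_var = np.ones((1, channels, 1))
        self.momentum = momentum
        self.eps = eps
        self._stats_seen = False

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2), keepdims=True)
            var = x.data.var(axis=(0, 2), keepdims=True)
            if not self._stats_seen:
                # seed the running averages with the first batch seen, so
                # evaluation mode is sane even after very few updates
                self.running_mean = mu.copy()
                self.running_var = var.copy()
                self._stats_seen = True
            else:
                self.running_mean = ((1 - self.momentum) * self.running_mean
                                     + self.momentum * mu)
                self.running_var = ((1 - self.momentum) * self.running_var
                                    + self.momentum * var)
        else:
            mu, var = self.running_mean, self.running_var
        return ag.batchnorm(x, self.gamma, self.beta, mu, var, self.eps,
                            batch_stats=self.training)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.add(ag.matmul(x, self.weight), self.bias)


class SEGate(Module):
    """Squeeze-and-excitation: global pool → bottleneck → logistic gate.

    ``override`` (testing hook) replaces the learned gate with a constant,
    e.g. 1.0 to reduce the SE-residual block to the plain residual block.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        hidden = max(channels // reduction, 1)
        self.fc1 = Dense(channels, hidden, rng)
        self.fc2 = Dense(hidden, channels, rng)
        self.override: float | None = None

    def __call__(self, x: Tensor) -> Tensor:
        if self.override is not None:
            b, c, _ = x.shape
            return Tensor(np.full((b, c, 1), self.override))
        squeezed = ag.mean(x, axis=2)  # (B, C)
        gate = ag.sigmoid(self.fc2(ag.relu(self.fc1(squeezed))))
        b, c = gate.shape
        return ag.reshape(gate, (b, c, 1))


class ResidualBlock(Module):
    """Conv1D→BN→ReLU→Conv1D→BN; shortcut from the first convolution's output.

    ``se`` adds the per-channel gate on the residual branch before the
    shortcut addition (the SE-residual variant).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, se: bool = False, reduction: int = 16):
        self.conv1 = Conv1d(c_in, c_out, kernel, rng)
        self.bn1 = BatchNorm1d(c_out)
        self.conv2 = Conv1d(c_out, c_out, kernel, rng)
        self.bn2 = BatchNorm1d(c_out)
        self.gate = SEGate(c_out, reduction, rng) if se else None

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[2] == 0:
            raise ValueError("zero-length feature map")
        shortcut = self.conv1(x)
        h = self.bn2(self.conv2(ag.relu(self.bn1(shortcut))))
        if self.gate is not None:
            h = ag.mul(h, self.gate(h))
        return ag.relu(ag.add(shortcut, h))


class InceptionBlock(Module):
    """Parallel convolutions of widths {1,3,5} + a pooled branch, projected."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.b1 = Conv1d(c_in, c_out, 1, rng)
        self.b3 = Conv1d(c_in, c_out, 3, rng)
        self.b5 = Conv1d(c_in, c_out, 5, rng)
        self.proj = Conv1d(3 * c_out + c_in, c_out, 1, rng)
        self.bn = BatchNorm1d(c_out)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[2] == 0:
            raise ValueError("zero-length feature map")
        pooled = ag.maxpool1d(x, kernel=3, stride=1, pad=1)
        cat = ag.concat([self.b1(x), self.b3(x), self.b5(x), pooled], axis=1)
        return ag.relu(self.bn(self.proj(cat)))


class UpsampleConv(Module):
    """Learned up-sampling: zero-interleave then convolve (transposed-conv style)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv = Conv1d(channels, channels, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(ag.zero_interleave(x, 2))
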