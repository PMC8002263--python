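"""1-D UNet++ classifier with nested dense skip pathways.

The network is a lattice of nodes X(i, j), where i is the down-sampling
level (0 at the input resolution) and j the position along the skip
pathway.  Encoder nodes X(i, 0) receive the max-pooled output of
X(i-1, 0); every decoder/skip node X(i, j>0) receives the channel-wise
concatenation of all same-level predecessors X(i, 0..j-1) and the
up-sampled output of X(i+1, j-1) — j+1 inputs in total.  The final node
X(0, L) is globally average-pooled per channel and a single logistic unit
emits the CHF likelihood.  Training minimises mean squared error between
that score and the {0, 1} cohort label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import (
    BatchNorm1d,
    Dense,
    InceptionBlock,
    Module,
    ResidualBlock,
    UpsampleConv,
)

BlockKind = Literal["se_residual", "residual", "inception"]

Node = tuple[int, int]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``depth`` is the number of down-sampling steps L; ``channels`` gives the
    per-level widths c_0..c_L; the deepest feature map has length M / 2**L
    where M is the (padded) input length.
    """

    depth: int = 4
    channels: tuple[int, ...] = (16, 32, 64, 128, 256)
    conv_kernel_width: int = 3
    se_reduction_ratio: int = 16
    block_kind: BlockKind = "se_residual"
    upsample_mode: Literal["nearest", "conv"] = "nearest"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be ≥ 1, got {self.depth}")
        if len(self.channels) != self.depth + 1:
            raise ValueError(
                f"need {self.depth + 1} channel widths for depth {self.depth}, "
                f"got {len(self.channels)}"
            )
        if any(c < 1 for c in self.channels):
            raise ValueError("channel widths must be positive")
        if self.conv_kernel_width % 2 != 1:
            raise ValueError("conv kernel width must be odd")
        if self.block_kind not in ("se_residual", "residual", "inception"):
            raise ValueError(f"unknown block kind {self.block_kind!r}")

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "channels": list(self.channels),
            "conv_kernel_width": self.conv_kernel_width,
            "se_reduction_ratio": self.se_reduction_ratio,
            "block_kind": self.block_kind,
            "upsample_mode": self.upsample_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        return cls(**d)


@dataclass(frozen=True)
class NodeGrid:
    """The UNet++ node lattice and its dependency structure."""

    depth: int
    nodes: frozenset[Node]
    # per node, ordered (kind, source) pairs; kind ∈ {input, down, skip, up}
    inputs: dict[Node, tuple[tuple[str, Node | None], ...]] = field(repr=False)
    topo_order: tuple[Node, ...] = ()

    def in_degree(self, node: Node) -> int:
        kinds = [k for k, _ in self.inputs[node] if k != "input"]
        return len(kinds)


def build_topology(depth: int) -> NodeGrid:
    """Enumerate nodes X(i, j), 0 ≤ i ≤ L, 0 ≤ j ≤ L - i, and their edges.

    The emitted topological order walks the skip columns left to right
    (j = 0..L, the encoder first), each column top-down — every node's
    inputs lie in earlier columns or earlier in its own row, so they
    always precede it.
    """
    if depth < 1:
        raise ValueError(f"depth must be ≥ 1, got {depth}")
    nodes = frozenset(
        (i, j) for i in range(depth + 1) for j in range(depth - i + 1)
    )
    inputs: dict[Node, tuple[tuple[str, Node | None], ...]] = {}
    for i, j in sorted(nodes):
        if (i, j) == (0, 0):
            inputs[(i, j)] = (("input", None),)
        elif j == 0:
            inputs[(i, j)] = (("down", (i - 1, 0)),)
        else:
            srcs = [("skip", (i, k)) for k in range(j)]
            srcs.append(("up", (i + 1, j - 1)))
            inputs[(i, j)] = tuple(srcs)
    order = tuple(
        (i, j)
        for j in range(depth + 1)
        for i in range(depth - j + 1)
    )
    return NodeGrid(depth=depth, nodes=nodes, inputs=inputs, topo_order=order)


def node_inputs(i: int, j: int, grid: NodeGrid) -> tuple[tuple[str, Node | None], ...]:
    """Ordered input sources of X(i, j): skips first, up-sampled last."""
    if (i, j) not in grid.nodes:
        raise ValueError(f"node ({i}, {j}) not in a depth-{grid.depth} grid")
    return grid.inputs[(i, j)]


class UNetPlusPlus1D(Module):
    """The classifier: node lattice of convolution blocks + GAP logistic head.

    Weights are seeded; the output head is zero-initialised so the untrained
    network scores every segment exactly 0.5.
    """

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        self.config = config or NetworkConfig()
        self.grid = build_topology(self.config.depth)
        rng = np.random.default_rng(seed)
        cfg = self.config
        self.blocks: dict[Node, Module] = {}
        self.upsamplers: dict[Node, Module] = {}
        for i, j in self.grid.topo_order:
            c_out = cfg.channels[i]
            if (i, j) == (0, 0):
                c_in = 1
            elif j == 0:
                c_in = cfg.channels[i - 1]
            else:
                c_in = j * c_out + cfg.channels[i + 1]
            self.blocks[(i, j)] = self._make_block(c_in, c_out, rng)
            if j > 0 and cfg.upsample_mode == "conv":
                self.upsamplers[(i, j)] = UpsampleConv(cfg.channels[i + 1], rng)
        # the pooled feature vector is batch-normalised before the logistic
        # unit (keeps the score distribution centred on 0.5 early in
        # training); the unit itself is zero-initialised
        self.head_norm = BatchNorm1d(cfg.channels[0])
        self.head = Dense(cfg.channels[0], 1, rng, zero_init=True)
        self._block_list = list(self.blocks.values())  # for parameters()
        self._upsampler_list = list(self.upsamplers.values())

    def _make_block(self, c_in: int, c_out: int, rng: np.random.Generator) -> Module:
        cfg = self.config
        if cfg.block_kind == "inception":
            return InceptionBlock(c_in, c_out, rng)
        return ResidualBlock(
            c_in,
            c_out,
            cfg.conv_kernel_width,
            rng,
            se=cfg.block_kind == "se_residual",
            reduction=cfg.se_reduction_ratio,
        )

    def _upsample(self, node: Node, x: Tensor) -> Tensor:
        if node in self.upsamplers:
            return self.upsamplers[node](x)
        return ag.upsample_nearest(x, 2)

    def forward(
        self, x: np.ndarray, return_features: bool = False
    ) -> Tensor | tuple[Tensor, dict[Node, Tensor]]:
        """Score a batch of padded segments.

        ``x``: (batch, M) or (batch, 1, M) with M a multiple of 2**depth.
        Returns the (batch,) tensor of CHF likelihoods in [0, 1].
        """
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[:, None, :]
        m = x.shape[2]
        if m % 2 ** self.config.depth != 0:
            raise ValueError(
                f"input length {m} is not a multiple of 2**{self.config.depth}; "
                "pad segments first"
            )
        feats: dict[Node, Tensor] = {}
        for i, j in self.grid.topo_order:
            srcs = self.grid.inputs[(i, j)]
            if srcs[0][0] == "input":
                inp = Tensor(x)
            elif srcs[0][0] == "down":
                inp = ag.maxpool1d(feats[srcs[0][1]], kernel=2, stride=2)
            else:
                parts = [feats[s] for k, s in srcs if k == "skip"]
                up_src = srcs[-1][1]
                parts.append(self._upsample((i, j), feats[up_src]))
                inp = ag.concat(parts, axis=1)
            feats[(i, j)] = self.blocks[(i, j)](inp)
        gap = ag.mean(feats[(0, self.config.depth)], axis=2)  # (B, c_0)
        b, c0 = gap.shape
        gap = ag.reshape(self.head_norm(ag.reshape(gap, (b, c0, 1))), (b, c0))
        score = ag.sigmoid(self.head(gap))
        score = ag.reshape(score, (x.shape[0],))
        if return_features:
            return score, feats
        return score

    __call__ = forward

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode scores as a plain array."""
        was_training = self.training
        self.set_training(False)
        try:
            return self.forward(x).data.copy()
        finally:
            self.set_training(was_training)

    # --- checkpointing -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        for idx, p in enumerate(self.parameters()):
            arrays[f"param_{idx}"] = p.data
        bn_idx = 0
        for m in self.modules():
            if hasattr(m, "running_mean"):
                arrays[f"bn_{bn_idx}_mean"] = m.running_mean
                arrays[f"bn_{bn_idx}_var"] = m.running_var
                bn_idx += 1
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for idx, p in enumerate(self.parameters()):
            p.data = np.asarray(arrays[f"param_{idx}"], dtype=np.float64)
        bn_idx = 0
        for m in self.modules():
            if hasattr(m, "running_mean"):
                m.running_mean = np.asarray(arrays[f"bn_{bn_idx}_mean"])
                m.running_var = np.asarray(arrays[f"bn_{bn_idx}_var"])
                bn_idx += 1

    def save(self, path) -> None:
        """Checkpoint with the full architecture config embedded."""
        import json

        np.savez(path, __config__=json.dumps(self.config.to_dict()),
                 **self.state_arrays())

    @classmethod
    def load(cls, path) -> "UNetPlusPlus1D":
        import json

        with np.load(path, allow_pickle=False) as data:
            cfg = NetworkConfig.from_dict(json.loads(str(data["__config__"])))
            model = cls(cfg)
            model.load_state_arrays({k: data[k] for k in data.files})
        return model


def mse_loss(labels: Sequence[float], scores: Sequence[float]) -> float:
    """Mean squared error (1/N) Σ (y_i − p_i)² between labels and scores."""
    y = np.asarray(labels, dtype=np.float64)
    p = np.asarray(scores, dtype=np.float64)
    if y.size == 0:
        raise ValueError("mse_loss requires at least one sample")
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {p.shape}")
    return float(np.mean((y - p) ** 2))


def mse_loss_tensor(labels: np.ndarray, scores: Tensor) -> Tensor:
    """Differentiable MSE used inside the training loop."""
    if labels.size == 0:
        raise ValueError("mse_loss requires at least one sample")
    diff = ag.sub(scores, Tensor(labels))
    return ag.mean(ag.pow_(diff, 2.0), axis=0)
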