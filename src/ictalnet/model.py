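"""The parallel ictal-net (PIN) architecture.

The network consumes a stack of n normalized scalograms (one per window of
a record) through n parallel convolutional blocks.  Each block is

    S x W input -> 3x3 valid convolution, F filters -> ECA channel gate
    -> ReLU -> 2x2 max-pool -> flatten -> 2-unit softmax head

The n two-unit head outputs are concatenated (length 2n) and classified by

    dense(432) -> ReLU -> batch norm -> dropout(0.7) -> dense(2) -> softmax

With the reference geometry (S=233, W=868, n=7, F=10, k_ECA=3, H=432) the
model holds exactly 6,981,109 parameters (including the per-unit batch-norm
running statistics), reproduced by both :func:`count_parameters` (closed
form) and the built network.

The standalone pre-training block is one branch with the same constructor,
used as a single-scalogram classifier before its weights are transferred
into every branch of the full network.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn


@dataclass
class PINConfig:
    """Complete architecture hyperparameter bundle."""

    n_blocks: int = 7            # = number of windows per record
    input_scales: int = 233      # S: CWT scales (input height)
    input_width: int = 868       # W: window length (input width)
    conv_filters: int = 10       # F
    conv_kernel: int = 3         # square, valid padding
    eca_k: int = 3               # bias-free ECA kernel length (odd)
    merge_units: int = 432       # H
    dropout_rate: float = 0.7
    n_classes: int = 2
    resize_to: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.resize_to is not None:
            self.resize_to = tuple(int(v) for v in self.resize_to)
            self.input_scales, self.input_width = self.resize_to
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        for name in ("input_scales", "input_width", "conv_filters",
                     "conv_kernel", "eca_k", "merge_units", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.eca_k % 2 == 0:
            raise ValueError("eca_k must be odd")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.input_scales < self.conv_kernel + 1 or self.input_width < self.conv_kernel + 1:
            raise ValueError(
                "input too small: convolution followed by 2x2 pooling would be empty"
            )

    # geometry helpers -------------------------------------------------
    @property
    def conv_out(self) -> tuple[int, int]:
        k = self.conv_kernel
        return self.input_scales - k + 1, self.input_width - k + 1

    @property
    def pool_out(self) -> tuple[int, int]:
        h, w = self.conv_out
        return h // 2, w // 2

    @property
    def flatten_len(self) -> int:
        h, w = self.pool_out
        if h < 1 or w < 1:
            raise ValueError("pooled feature map is empty")
        return h * w * self.conv_filters

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PINConfig":
        d = json.loads(Path(path).read_text())
        if d.get("resize_to") is not None:
            d["resize_to"] = tuple(d["resize_to"])
        return cls(**d)


def _block_layers(config: PINConfig, rng: np.random.Generator) -> list[nn.Layer]:
    return [
        nn.Conv2DValid(config.conv_filters, config.conv_kernel, rng),
        nn.ECAGate(config.eca_k, rng),
        nn.ReLU(),
        nn.MaxPool2x2(),
        nn.Flatten(),
        nn.Dense(config.flatten_len, config.n_classes, rng),
        nn.Softmax(),
    ]


def build_block(config: PINConfig, rng: np.random.Generator | int = 0) -> nn.Sequential:
    """One convolutional branch: conv -> ECA -> ReLU -> pool -> softmax head."""
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    return nn.Sequential(_block_layers(config, rng))


class BlockNet:
    """Standalone single-block classifier used for pre-training.

    Consumes one scalogram (batch, S, W); emits class probabilities.
    """

    def __init__(self, config: PINConfig, rng: np.random.Generator | int = 0):
        if isinstance(rng, int):
            rng = np.random.default_rng(rng)
        self.config = config
        self.block = build_block(config, rng)

    def params(self):
        return self.block.params()

    def state_arrays(self):
        return self.block.state_arrays()

    def n_parameters(self) -> int:
        return _count_arrays(self)

    def forward_logits(self, x, training=False, rng=None):
        for layer in self.block.layers[:-1]:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def forward(self, x, training=False, rng=None):
        return nn.softmax(self.forward_logits(x, training=training, rng=rng))

    def backward_from_logits(self, grad):
        for layer in reversed(self.block.layers[:-1]):
            grad = layer.backward(grad)
        return grad

    def predict_proba(self, x, batch_size=64):
        return _batched_predict(self, x, batch_size)


class PINNetwork:
    """The full parallel network: n branches plus the merge classifier."""

    def __init__(self, config: PINConfig, rng: np.random.Generator | int = 0):
        if isinstance(rng, int):
            rng = np.random.default_rng(rng)
        self.config = config
        c = config
        self.blocks = [nn.Sequential(_block_layers(c, rng)) for _ in range(c.n_blocks)]
        merged = c.n_classes * c.n_blocks
        self.merge = nn.Sequential(
            [
                nn.Dense(merged, c.merge_units, rng),
                nn.ReLU(),
                nn.BatchNorm1D(c.merge_units),
                nn.Dropout(c.dropout_rate),
                nn.Dense(c.merge_units, c.n_classes, rng),
            ]
        )

    def params(self):
        return [p for b in self.blocks for p in b.params()] + self.merge.params()

    def state_arrays(self):
        return [a for b in self.blocks for a in b.state_arrays()] + self.merge.state_arrays()

    def n_parameters(self) -> int:
        return _count_arrays(self)

    def forward_logits(self, x, training=False, rng=None):
        # x: (batch, n_blocks, S, W) — one scalogram per branch
        if x.shape[1] != self.config.n_blocks:
            raise ValueError(
                f"stack has {x.shape[1]} windows but the model has "
                f"{self.config.n_blocks} branches"
            )
        feats = [
            b.forward(x[:, j], training=training, rng=rng)
            for j, b in enumerate(self.blocks)
        ]
        merged = np.concatenate(feats, axis=1)
        return self.merge.forward(merged, training=training, rng=rng)

    def forward(self, x, training=False, rng=None):
        return nn.softmax(self.forward_logits(x, training=training, rng=rng))

    def backward_from_logits(self, grad):
        gm = self.merge.backward(grad)
        k = self.config.n_classes
        for j, b in enumerate(self.blocks):
            b.backward(gm[:, j * k : (j + 1) * k])

    def predict_proba(self, x, batch_size=32):
        return _batched_predict(self, x, batch_size)


def _batched_predict(net, x, batch_size):
    outs = [
        net.forward(x[i : i + batch_size].astype(nn.DTYPE))
        for i in range(0, len(x), batch_size)
    ]
    return np.concatenate(outs, axis=0)


def _count_arrays(net) -> int:
    return int(
        sum(p.value.size for p in net.params())
        + sum(a.size for a in net.state_arrays())
    )


def build_pretrain_block(config: PINConfig, rng: np.random.Generator | int = 0) -> BlockNet:
    return BlockNet(config, rng)


def build_pin(config: PINConfig, rng: np.random.Generator | int = 0) -> PINNetwork:
    return PINNetwork(config, rng)


def count_parameters(config: PINConfig) -> int:
    """Closed-form parameter count of the full network.

    Per block: a k x k single-channel convolution with bias (k^2 F + F), the
    bias-free ECA kernel (k_ECA), and the flattened softmax head
    (flatten_len * n_classes + n_classes).  The merge path adds the 432-unit
    dense layer, four batch-norm terms per unit (gamma, beta, running mean,
    running variance) and the output layer.
    """
    c = config
    k2 = c.conv_kernel**2
    block = (
        (k2 * c.conv_filters + c.conv_filters)
        + c.eca_k
        + (c.flatten_len * c.n_classes + c.n_classes)
    )
    merge = c.n_classes * c.n_blocks * c.merge_units + c.merge_units
    bn = 4 * c.merge_units
    out = c.merge_units * c.n_classes + c.n_classes
    return c.n_blocks * block + merge + bn + out


def count_parameters_block(config: PINConfig) -> int:
    """Closed-form count for the standalone pre-training block."""
    c = config
    return (
        c.conv_kernel**2 * c.conv_filters
        + c.conv_filters
        + c.eca_k
        + c.flatten_len * c.n_classes
        + c.n_classes
    )


# ---------------------------------------------------------------- weights io

def save_weights(net, path: str | Path) -> None:
    """Serialize all parameter and state arrays to an .npz checkpoint."""
    arrays = {f"p{i}": p.value for i, p in enumerate(net.params())}
    arrays.update({f"s{i}": a for i, a in enumerate(net.state_arrays())})
    np.savez(path, **arrays)


def load_weights(net, path: str | Path) -> None:
    with np.load(path) as data:
        for i, p in enumerate(net.params()):
            arr = data[f"p{i}"]
            if arr.shape != p.value.shape:
                raise ValueError(
                    f"checkpoint mismatch at parameter {i}: "
                    f"{arr.shape} vs {p.value.shape}"
                )
            p.value[:] = arr
        for i, a in enumerate(net.state_arrays()):
            a[:] = data[f"s{i}"]
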