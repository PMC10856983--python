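"""Channel-attention operators.

Two gates over the per-channel global averages y of a feature map:

* ECA (efficient channel attention):  f_c = sigmoid(conv(y)) — a bias-free
  1-D convolution of length-k (k odd, default 3) across the channel axis,
  zero-padded to keep the length.  This is the gate used inside every
  network block; it costs exactly k parameters.
* squeeze-and-excitation:  f_c = sigmoid(W2 @ relu(W1 @ y)) — the two-layer
  bottleneck alternative, kept for ablation.

Feature maps are H x W x C (channels last).  The module output is the input
map with channel c scaled by f_c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d

DEFAULT_ECA_KERNEL_SIZE = 3


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class ECAParams:
    """Bias-free 1-D convolution kernel of odd length k (default 3)."""

    kernel: np.ndarray

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=np.float64)
        if self.kernel.ndim != 1 or self.kernel.size % 2 == 0:
            raise ValueError("ECA kernel must be 1-D with odd length")

    @property
    def n_parameters(self) -> int:
        return int(self.kernel.size)


@dataclass
class SEParams:
    """Squeeze-and-excitation weights: W1 (C/r x C), W2 (C x C/r)."""

    W1: np.ndarray
    W2: np.ndarray

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=np.float64)
        self.W2 = np.asarray(self.W2, dtype=np.float64)
        if self.W1.ndim != 2 or self.W2.ndim != 2:
            raise ValueError("W1 and W2 must be matrices")
        if self.W1.shape[0] != self.W2.shape[1] or self.W1.shape[1] != self.W2.shape[0]:
            raise ValueError("W1 and W2 shapes are inconsistent")


def squeeze(feature_map: np.ndarray) -> np.ndarray:
    """Global mean over the spatial axes: (H, W, C) -> y of length C."""
    fm = np.asarray(feature_map, dtype=np.float64)
    if fm.ndim != 3 or fm.size == 0:
        raise ValueError("feature map must be a non-empty H x W x C array")
    return fm.mean(axis=(0, 1))


def eca_gate(y: np.ndarray, params: ECAParams) -> np.ndarray:
    """sigmoid of the zero-padded 1-D cross-correlation of y with the kernel."""
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("y must be a non-empty vector")
    pre = correlate1d(y, params.kernel, mode="constant", cval=0.0)
    return sigmoid(pre)


def se_gate(y: np.ndarray, params: SEParams) -> np.ndarray:
    """sigmoid(W2 @ relu(W1 @ y))."""
    y = np.asarray(y, dtype=np.float64)
    if params.W1.shape[1] != y.size or params.W2.shape[0] != y.size:
        raise ValueError(
            f"weight shapes {params.W1.shape}/{params.W2.shape} do not match C={y.size}"
        )
    hidden = np.maximum(params.W1 @ y, 0.0)
    return sigmoid(params.W2 @ hidden)


def apply_gate(feature_map: np.ndarray, gate: np.ndarray) -> np.ndarray:
    """Scale channel c of an (H, W, C) map by gate[c]."""
    fm = np.asarray(feature_map, dtype=np.float64)
    gate = np.asarray(gate, dtype=np.float64)
    if fm.ndim != 3 or gate.ndim != 1 or fm.shape[2] != gate.size:
        raise ValueError("gate length must equal the channel count")
    return fm * gate[None, None, :]
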