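"""Three-stage training protocol: pre-train, transfer, train.

1. *Pre-train*: every record's scalogram stack is exploded into its n
   individual labelled scalograms (m records yield m*n items) and a
   standalone single-block classifier is trained on them.
2. *Transfer*: the pre-trained block's weights (convolution kernel/bias,
   ECA kernel, softmax-head weights) are copied into every branch of the
   full parallel network; the merge classifier keeps its fresh
   initialization.  Transferred layers remain trainable unless frozen.
3. *Train*: mini-batch training (batch 32, up to 150 epochs) of the full
   network, with early stopping as soon as training-set accuracy reaches
   100% (evaluated over the whole training set at each epoch end).

All randomness — weight init, shuffling, dropout — derives from
``TrainSpec.seed``, so identical specs give identical weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import BlockNet, PINConfig, PINNetwork
from .preprocess import ScalogramStack

LABEL_TO_INDEX = {"interictal": 0, "ictal": 1}


@dataclass
class TrainSpec:
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 150
    early_stop: bool = True  # stop at 100% training accuracy
    seed: int = 0
    freeze_transferred: bool = False

    def __post_init__(self) -> None:
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class TrainReport:
    epochs_run: int
    final_train_accuracy: float
    loss_history: list[float]
    stopped_early: bool


def stacks_to_arrays(stacks: list[ScalogramStack]) -> tuple[np.ndarray, np.ndarray]:
    """(N, n_windows, S, W) float32 inputs and integer labels."""
    if not stacks:
        raise ValueError("no scalogram stacks given")
    X = np.stack([s.tensor.transpose(2, 0, 1) for s in stacks]).astype(nn.DTYPE)
    try:
        y = np.array([LABEL_TO_INDEX[s.label] for s in stacks])
    except KeyError:
        raise ValueError("all records must be labelled ictal or interictal") from None
    return X, y


def _one_hot(y: np.ndarray, k: int = 2) -> np.ndarray:
    out = np.zeros((y.size, k), dtype=nn.DTYPE)
    out[np.arange(y.size), y] = 1.0
    return out


def _train_loop(net, X, y, spec: TrainSpec, params) -> TrainReport:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(1,)))
    opt = nn.make_optimizer(spec.optimizer, params, spec.learning_rate)
    onehot = _one_hot(y)
    n = len(X)
    history: list[float] = []
    epochs_run = 0
    stopped_early = False
    acc = _accuracy(net, X, y)
    for epoch in range(spec.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, yb = X[idx], onehot[idx]
            logits = net.forward_logits(xb, training=True, rng=rng)
            probs = nn.softmax(logits)
            eps = 1e-12
            epoch_loss -= float(
                np.sum(yb * np.log(probs + eps))
            )
            nn.zero_grads(params)
            net.backward_from_logits((probs - yb) / len(idx))
            opt.step()
        history.append(epoch_loss / n)
        epochs_run = epoch + 1
        acc = _accuracy(net, X, y)
        if spec.early_stop and acc == 1.0:
            stopped_early = True
            break
    return TrainReport(
        epochs_run=epochs_run,
        final_train_accuracy=acc,
        loss_history=history,
        stopped_early=stopped_early,
    )


def _accuracy(net, X, y) -> float:
    probs = net.predict_proba(X)
    return float(np.mean(probs.argmax(axis=1) == y))


def pretrain(
    stacks: list[ScalogramStack], config: PINConfig, spec: TrainSpec
) -> tuple[BlockNet, TrainReport]:
    """Train the standalone block on individual labelled scalograms."""
    X, y = stacks_to_arrays(stacks)
    n_windows = X.shape[1]
    # explode: m stacks of n windows -> m*n single-scalogram items
    Xf = X.reshape(-1, X.shape[2], X.shape[3])
    yf = np.repeat(y, n_windows)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(0,)))
    block = BlockNet(config, rng)
    report = _train_loop(block, Xf, yf, spec, block.params())
    return block, report


def transfer(block: BlockNet, pin: PINNetwork) -> PINNetwork:
    """Copy the pre-trained block's weights into every branch of the PIN."""
    src = block.params()
    for branch in pin.blocks:
        dst = branch.params()
        if len(src) != len(dst):
            raise ValueError("block and branch layer inventories differ")
        for s, d in zip(src, dst):
            if s.value.shape != d.value.shape:
                raise ValueError(
                    f"shape mismatch during transfer: {s.value.shape} vs {d.value.shape}"
                )
            d.value[:] = s.value
    return pin


def train(
    pin: PINNetwork, stacks: list[ScalogramStack], spec: TrainSpec
) -> tuple[PINNetwork, TrainReport]:
    """Mini-batch training of the full network with early stopping."""
    X, y = stacks_to_arrays(stacks)
    if len(stacks) < 2 or len(np.unique(y)) < 2:
        raise ValueError("training needs records of both classes")
    params = pin.merge.params() if spec.freeze_transferred else pin.params()
    report = _train_loop(pin, X, y, spec, params)
    return pin, report


def fit_pipeline(
    train_stacks: list[ScalogramStack],
    config: PINConfig,
    spec: TrainSpec,
) -> tuple[PINNetwork, TrainReport, TrainReport]:
    """Full protocol: pretrain -> build PIN -> transfer -> train."""
    block, pre_report = pretrain(train_stacks, config, spec)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(2,)))
    pin = PINNetwork(config, rng)
    transfer(block, pin)
    pin, report = train(pin, train_stacks, spec)
    return pin, pre_report, report


def predict_labels(pin, stacks: list[ScalogramStack]) -> list[str]:
    X, _ = _inputs_only(stacks)
    probs = pin.predict_proba(X)
    inv = {v: k for k, v in LABEL_TO_INDEX.items()}
    return [inv[int(i)] for i in probs.argmax(axis=1)]


def _inputs_only(stacks):
    X = np.stack([s.tensor.transpose(2, 0, 1) for s in stacks]).astype(nn.DTYPE)
    return X, None
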