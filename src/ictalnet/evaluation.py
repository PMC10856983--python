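"""Confusion-matrix metrics and validation protocols.

The positive class is *ictal*.  From TP/FP/TN/FN counts:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

A metric whose denominator is zero is reported as 0, which keeps fold
averaging total.  Three protocols are provided: stratified k-fold
cross-validation (default k=10), a stratified 70/30 holdout, and grouped
leave-one-subject-out; the splitters are deterministic given their seed.
The classification unit is the record — one scalogram stack, one prediction.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import (
    LeaveOneGroupOut,
    StratifiedKFold,
    train_test_split,
)

from .model import PINConfig, PINNetwork
from .preprocess import ScalogramStack
from .training import (
    LABEL_TO_INDEX,
    TrainSpec,
    fit_pipeline,
    stacks_to_arrays,
)

POSITIVE_LABEL = "ictal"


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }

    def mean(self) -> float:
        return (self.accuracy + self.precision + self.recall + self.f1) / 4.0


def confusion(predictions, truth) -> ConfusionMatrix:
    """Count TP/FP/TN/FN with ictal as the positive class."""
    predictions = list(predictions)
    truth = list(truth)
    if len(predictions) != len(truth) or not truth:
        raise ValueError("predictions and truth must have equal, non-zero length")
    cm = ConfusionMatrix()
    for p, t in zip(predictions, truth):
        pos_p = _is_positive(p)
        pos_t = _is_positive(t)
        if pos_t and pos_p:
            cm.tp += 1
        elif pos_t and not pos_p:
            cm.fn += 1
        elif not pos_t and pos_p:
            cm.fp += 1
        else:
            cm.tn += 1
    return cm


def _is_positive(label) -> bool:
    if isinstance(label, str):
        return label == POSITIVE_LABEL
    return bool(label)


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Accuracy, precision, recall and F1 from the counts."""
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    acc = (cm.tp + cm.tn) / cm.total
    prec = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) else 0.0
    rec = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else 0.0
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
    return MetricReport(accuracy=acc, precision=prec, recall=rec, f1=f1)


def mean_report(reports: list[MetricReport]) -> MetricReport:
    if not reports:
        raise ValueError("no reports to average")
    return MetricReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
    )


def stratified_kfold(labels, k: int = 10, seed: int = 0):
    """Disjoint, exhaustive, class-balanced index folds (list of arrays)."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members; need >= k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def holdout_split(labels, train_fraction: float = 0.70, seed: int = 0):
    """Stratified train/test index split at the given fraction."""
    labels = np.asarray(labels)
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=labels, random_state=seed
    )
    return np.sort(train_idx), np.sort(test_idx)


def grouped_loso(group_ids):
    """One fold per distinct group: (train indices, test indices) pairs."""
    groups = np.asarray(group_ids, dtype=object)
    if any(g is None or g == "" for g in groups):
        raise ValueError("every record needs a group_id for LOSO")
    if len(set(groups.tolist())) < 2:
        raise ValueError("LOSO needs at least two distinct groups")
    logo = LeaveOneGroupOut()
    return [
        (train, test)
        for train, test in logo.split(np.zeros(len(groups)), groups=groups)
    ]


@dataclass
class CVResult:
    fold_reports: list[MetricReport]
    mean: MetricReport
    confusion_total: ConfusionMatrix
    l2: float  # pooled MSE between one-hot labels and predicted probabilities
    train_time_s: float


def _evaluate_fold(stacks, train_idx, test_idx, config, spec):
    train_stacks = [stacks[i] for i in train_idx]
    test_stacks = [stacks[i] for i in test_idx]
    pin, _, _ = fit_pipeline(train_stacks, config, spec)
    X, y = stacks_to_arrays(test_stacks)
    probs = pin.predict_proba(X)
    pred = probs.argmax(axis=1)
    cm = confusion(pred, y)
    onehot = np.zeros_like(probs)
    onehot[np.arange(len(y)), y] = 1.0
    sq = float(np.sum((probs - onehot) ** 2))
    return cm, sq, probs.size


def cross_validate(
    stacks: list[ScalogramStack],
    config: PINConfig,
    spec: TrainSpec,
    k: int = 10,
    seed: int | None = None,
) -> CVResult:
    """Stratified k-fold CV of the full pretrain->transfer->train pipeline.

    Each fold's training split gets its own derived seed
    (``spec.seed + fold_index``); reported metrics are the arithmetic mean
    over folds.
    """
    labels = [s.label for s in stacks]
    folds = stratified_kfold(labels, k=k, seed=spec.seed if seed is None else seed)
    all_idx = np.arange(len(stacks))
    reports = []
    total = ConfusionMatrix()
    sq_sum, n_prob = 0.0, 0
    t0 = time.perf_counter()
    for fold_i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        fold_spec = TrainSpec(**{**spec.__dict__, "seed": spec.seed + fold_i})
        cm, sq, np_ = _evaluate_fold(stacks, train_idx, test_idx, config, fold_spec)
        reports.append(metrics(cm))
        total.tp += cm.tp
        total.fp += cm.fp
        total.tn += cm.tn
        total.fn += cm.fn
        sq_sum += sq
        n_prob += np_
    return CVResult(
        fold_reports=reports,
        mean=mean_report(reports),
        confusion_total=total,
        l2=sq_sum / n_prob if n_prob else 0.0,
        train_time_s=time.perf_counter() - t0,
    )


def evaluate_holdout(
    stacks, config, spec, train_fraction: float = 0.70
) -> tuple[MetricReport, ConfusionMatrix]:
    """Single stratified holdout evaluation of the full pipeline."""
    labels = [s.label for s in stacks]
    train_idx, test_idx = holdout_split(labels, train_fraction, seed=spec.seed)
    cm, _, _ = _evaluate_fold(stacks, train_idx, test_idx, config, spec)
    return metrics(cm), cm


def evaluate_loso_groups(
    stacks, group_ids, config, spec
) -> tuple[list[MetricReport], MetricReport]:
    """LOSO with caller-supplied group ids (one per stack)."""
    folds = grouped_loso(group_ids)
    reports = []
    for fold_i, (train_idx, test_idx) in enumerate(folds):
        fold_spec = TrainSpec(**{**spec.__dict__, "seed": spec.seed + fold_i})
        cm, _, _ = _evaluate_fold(stacks, train_idx, test_idx, config, fold_spec)
        reports.append(metrics(cm))
    return reports, mean_report(reports)
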