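import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ictalnet.evaluation import (
    ConfusionMatrix,
    confusion,
    cross_validate,
    grouped_loso,
    holdout_split,
    mean_report,
    metrics,
    stratified_kfold,
)
from ictalnet.training import TrainSpec


def test_confusion_all_correct():
    truth = ["ictal"] * 10 + ["interictal"] * 10
    cm = confusion(truth, truth)
    assert (cm.tp, cm.tn, cm.fp, cm.fn) == (10, 10, 0, 0)


def test_confusion_flip_symmetry():
    truth = ["ictal"] * 3 + ["interictal"] * 5
    flipped = ["interictal"] * 3 + ["ictal"] * 5
    cm = confusion(flipped, truth)
    assert (cm.tp, cm.fn, cm.tn, cm.fp) == (0, 3, 0, 5)


def test_confusion_length_mismatch():
    with pytest.raises(ValueError):
        confusion(["ictal"], ["ictal", "interictal"])


@given(st.integers(0, 100_000))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_confusion_matches_pair_counting_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 60))
    truth = rng.integers(0, 2, size=n)
    pred = rng.integers(0, 2, size=n)
    cm = confusion(pred, truth)
    assert cm.tp == int(np.sum((truth == 1) & (pred == 1)))
    assert cm.tn == int(np.sum((truth == 0) & (pred == 0)))
    assert cm.fp == int(np.sum((truth == 0) & (pred == 1)))
    assert cm.fn == int(np.sum((truth == 1) & (pred == 0)))


def test_metrics_hand_case():
    r = metrics(ConfusionMatrix(tp=50, tn=40, fp=10, fn=0))
    assert r.accuracy == pytest.approx(0.90)
    assert r.precision == pytest.approx(50 / 60)
    assert r.recall == 1.0
    assert r.f1 == pytest.approx(2 * (50 / 60) / (50 / 60 + 1))
    assert r.f1 == pytest.approx(0.909090909, abs=1e-6)


def test_metrics_perfect_and_degenerate():
    perfect = metrics(ConfusionMatrix(tp=5, tn=5, fp=0, fn=0))
    assert (perfect.accuracy, perfect.precision, perfect.recall, perfect.f1) == (1, 1, 1, 1)
    none_pos = metrics(ConfusionMatrix(tp=0, tn=4, fp=0, fn=0))
    assert none_pos.precision == 0.0 and none_pos.recall == 0.0 and none_pos.f1 == 0.0
    with pytest.raises(ValueError):
        metrics(ConfusionMatrix())


@given(st.integers(0, 100_000))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_metrics_match_sklearn_oracle(seed):
    """Independent cross-check of the four formulas against scikit-learn."""
    from sklearn.metrics import (
        accuracy_score,
        f1_score,
        precision_score,
        recall_score,
    )

    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 80))
    truth = rng.integers(0, 2, size=n)
    pred = rng.integers(0, 2, size=n)
    r = metrics(confusion(pred, truth))
    assert r.accuracy == pytest.approx(accuracy_score(truth, pred))
    assert r.precision == pytest.approx(precision_score(truth, pred, zero_division=0))
    assert r.recall == pytest.approx(recall_score(truth, pred, zero_division=0))
    assert r.f1 == pytest.approx(f1_score(truth, pred, zero_division=0))


def test_truth_vs_itself_gives_all_ones():
    truth = ["ictal", "interictal", "ictal"]
    r = metrics(confusion(truth, truth))
    assert r.accuracy == r.precision == r.recall == r.f1 == 1.0


# ------------------------------------------------------------- splitters

def test_stratified_10fold_on_200_balanced():
    labels = ["ictal", "interictal"] * 100
    folds = stratified_kfold(labels, k=10, seed=0)
    assert len(folds) == 10
    labels_arr = np.array(labels)
    for fold in folds:
        assert len(fold) == 20
        assert np.sum(labels_arr[fold] == "ictal") == 10
        assert len(labels) - len(fold) == 180  # training records per fold
    # disjoint and exhaustive
    union = np.concatenate(folds)
    assert len(union) == 200
    assert len(np.unique(union)) == 200


def test_kfold_k_equals_class_size_and_errors():
    labels = ["ictal"] * 4 + ["interictal"] * 4
    folds = stratified_kfold(labels, k=4, seed=1)
    labels_arr = np.array(labels)
    for fold in folds:
        assert np.sum(labels_arr[fold] == "ictal") == 1
    with pytest.raises(ValueError):
        stratified_kfold(labels, k=5, seed=0)
    with pytest.raises(ValueError):
        stratified_kfold(labels, k=1, seed=0)


@given(st.integers(0, 10_000))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_fold_partition_property(seed):
    rng = np.random.default_rng(seed)
    n_pos = int(rng.integers(6, 40))
    n_neg = int(rng.integers(6, 40))
    labels = np.array(["ictal"] * n_pos + ["interictal"] * n_neg)
    labels = labels[rng.permutation(len(labels))]
    k = int(rng.integers(2, min(n_pos, n_neg) + 1))
    folds = stratified_kfold(labels, k=k, seed=seed)
    union = np.concatenate(folds)
    assert len(np.unique(union)) == len(labels) == len(union)
    pos_counts = [int(np.sum(labels[f] == "ictal")) for f in folds]
    assert max(pos_counts) - min(pos_counts) <= 1


def test_kfold_deterministic_given_seed():
    labels = ["ictal", "interictal"] * 30
    a = stratified_kfold(labels, k=5, seed=3)
    b = stratified_kfold(labels, k=5, seed=3)
    for fa, fb in zip(a, b):
        np.testing.assert_array_equal(fa, fb)


def test_holdout_70_30_stratified():
    labels = np.array(["ictal", "interictal"] * 100)
    train_idx, test_idx = holdout_split(labels, 0.70, seed=0)
    assert len(train_idx) == 140 and len(test_idx) == 60
    assert np.sum(labels[train_idx] == "ictal") == 70
    assert np.sum(labels[test_idx] == "ictal") == 30
    assert len(np.intersect1d(train_idx, test_idx)) == 0


def test_grouped_loso_folds():
    groups = [f"subj{i % 10}" for i in range(40)]
    folds = grouped_loso(groups)
    assert len(folds) == 10
    for train_idx, test_idx in folds:
        test_groups = {groups[i] for i in test_idx}
        assert len(test_groups) == 1
        assert test_groups.isdisjoint({groups[i] for i in train_idx})
    with pytest.raises(ValueError):
        grouped_loso(["only-one"] * 5)
    with pytest.raises(ValueError):
        grouped_loso(["a", None, "b"])


# ------------------------------------------------------------- pipeline CV

def test_cross_validate_smallest_case(tiny_stacks, tiny_config):
    spec = TrainSpec(seed=0, max_epochs=1)
    result = cross_validate(tiny_stacks[:4], tiny_config, spec, k=2)
    assert len(result.fold_reports) == 2
    assert result.confusion_total.total == 4
    assert result.l2 >= 0
    assert 0 <= result.mean.accuracy <= 1


def test_cross_validate_deterministic(tiny_stacks, tiny_config):
    spec = TrainSpec(seed=2, max_epochs=2, learning_rate=1e-3)
    a = cross_validate(tiny_stacks, tiny_config, spec, k=2)
    b = cross_validate(tiny_stacks, tiny_config, spec, k=2)
    assert a.mean.as_dict() == b.mean.as_dict()
    assert a.l2 == b.l2


def test_mean_report_is_arithmetic_mean():
    from ictalnet.evaluation import MetricReport

    r = mean_report([
        MetricReport(1.0, 0.5, 0.0, 0.25),
        MetricReport(0.0, 0.5, 1.0, 0.75),
    ])
    assert r.accuracy == 0.5 and r.precision == 0.5
    assert r.recall == 0.5 and r.f1 == 0.5
    with pytest.raises(ValueError):
        mean_report([])
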