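"""Stratified splitting, classification reports, and the CNN->SVM trainer."""

import numpy as np
import pytest

from evsig.core_io import CLASS_ORDER, FourClassLabel
from evsig.hybrid import CnnConfig, classification_report, train_hybrid
from evsig.split import stratified_split


def test_stratified_split_proportions():
    labels = (
        [FourClassLabel.NORMAL] * 30
        + [FourClassLabel.OTHER_SUBTYPE] * 57
        + [FourClassLabel.TNBC_NO_RECUR] * 26
        + [FourClassLabel.TNBC_RECUR] * 17
    )
    ids = [f"S{i:03d}" for i in range(130)]
    split = stratified_split(ids, labels, 0.7, seed=0)
    assert abs(len(split.train_ids) - 91) <= 2
    assert set(split.train_ids) | set(split.test_ids) == set(ids)
    by_id = dict(zip(ids, labels))
    for cls in CLASS_ORDER:
        n_tr = sum(by_id[s] == cls for s in split.train_ids)
        n_te = sum(by_id[s] == cls for s in split.test_ids)
        assert n_tr >= 1 and n_te >= 1
        total = n_tr + n_te
        assert abs(n_tr - 0.7 * total) <= 1


def test_stratified_split_errors_and_determinism():
    ids = ["a", "b", "c", "d"]
    labels = ["x", "x", "y", "y"]
    s1 = stratified_split(ids, labels, 0.5, seed=3)
    s2 = stratified_split(ids, labels, 0.5, seed=3)
    assert s1.train_ids == s2.train_ids and s1.test_ids == s2.test_ids
    with pytest.raises(ValueError, match="fraction_train"):
        stratified_split(ids, labels, 1.0)
    with pytest.raises(ValueError, match="single sample"):
        stratified_split(["a", "b", "c"], ["x", "x", "y"], 0.5)


def test_report_perfect_and_degenerate():
    t = ["A", "A", "B", "B", "C"]
    rep = classification_report(t, t, classes=["A", "B", "C"])
    assert rep.accuracy == 1.0
    assert np.array_equal(rep.confusion, np.diag([2, 2, 1]))
    assert np.allclose(rep.per_class_tpr, 1.0)
    assert np.allclose(rep.per_class_tpr + rep.per_class_fnr, 1.0)

    allsame = classification_report(t, ["A"] * 5, classes=["A", "B", "C"])
    assert allsame.per_class_tpr[0] == 1.0
    assert allsame.per_class_tpr[1] == 0.0 and allsame.per_class_tpr[2] == 0.0

    with pytest.raises(ValueError, match="outside"):
        classification_report(["A"], ["Z"], classes=["A", "B"])


def test_report_hand_built_counts_and_auc():
    true = ["A", "A", "A", "A", "B", "B", "B", "B", "C", "C", "C", "C"]
    pred = ["A", "A", "B", "C", "B", "B", "B", "A", "C", "C", "A", "C"]
    scores = np.zeros((12, 3))
    rng = np.random.default_rng(0)
    scores[:, 0] = [0.9, 0.8, 0.2, 0.3, 0.1, 0.2, 0.15, 0.6, 0.1, 0.05, 0.55, 0.2]
    scores[:, 1] = rng.random(12)
    scores[:, 2] = rng.random(12)
    rep = classification_report(true, pred, scores, classes=["A", "B", "C"])
    expected_confusion = np.array([[2, 1, 1], [1, 3, 0], [1, 0, 3]])
    assert np.array_equal(rep.confusion, expected_confusion)
    assert rep.accuracy == pytest.approx(8 / 12)
    # AUC for class A by exhaustive pairwise concordance
    pos = scores[:4, 0]
    neg = scores[4:, 0]
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg) / (4 * 8)
    assert rep.per_class_auc[0] == pytest.approx(conc, abs=1e-12)
    assert rep.confusion.sum(axis=1).tolist() == [4, 4, 4]


def test_report_relabel_invariance(rng):
    true = list(rng.choice(["A", "B", "C"], size=30))
    pred = list(rng.choice(["A", "B", "C"], size=30))
    rep1 = classification_report(true, pred, classes=["A", "B", "C"])
    swap = {"A": "Z1", "B": "Z2", "C": "Z3"}
    rep2 = classification_report(
        [swap[t] for t in true], [swap[p] for p in pred], classes=["Z1", "Z2", "Z3"]
    )
    assert np.array_equal(rep1.confusion, rep2.confusion)
    assert rep1.accuracy == rep2.accuracy


def _fast_cnn(seed=0):
    return CnnConfig(epochs=30, n_ensemble=1, seed=seed)


def test_train_hybrid_determinism_and_leakage(small_imputed):
    matrix, annotations, labels = small_imputed
    model1, rep1 = train_hybrid(matrix, labels, cnn_config=_fast_cnn(), seed=4)
    model2, rep2 = train_hybrid(matrix, labels, cnn_config=_fast_cnn(), seed=4)
    assert np.array_equal(rep1.confusion, rep2.confusion)
    assert np.allclose(rep1.per_class_auc, rep2.per_class_auc, equal_nan=True)
    # id audit: test metrics only from held-out ids
    assert set(model1.split.train_ids).isdisjoint(model1.split.test_ids)
    assert rep1.confusion.sum() == len(model1.split.test_ids)
    assert model1.train_report.confusion.sum() == len(model1.split.train_ids)


def test_train_hybrid_single_class_error(small_imputed):
    matrix, annotations, labels = small_imputed
    from evsig.split import SplitSpec

    normals = [a.sample_id for a, l in zip(annotations, labels) if l == FourClassLabel.NORMAL]
    others = [s for s in matrix.sample_ids if s not in normals]
    split = SplitSpec(normals, others, 0.5, False, 0)
    with pytest.raises(ValueError, match="Normal"):
        train_hybrid(matrix, labels, split=split, cnn_config=_fast_cnn(), seed=0)


def test_train_hybrid_dense_fallback(small_imputed):
    matrix, annotations, labels = small_imputed
    subset = matrix.protein_ids[:3]  # below the convolutional minimum of 4
    model, rep = train_hybrid(
        matrix, labels, marker_subset=subset, cnn_config=_fast_cnn(), seed=1
    )
    assert all(c.dense_only for c in model.cnns)
    assert 0.0 <= rep.accuracy <= 1.0
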