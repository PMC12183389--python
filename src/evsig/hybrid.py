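"""Hybrid CNN -> SVM four-class classifier.

A small 1-D convolutional network runs along the biomarker axis of each
sample; its penultimate dense layer (the "activation map") is the feature
vector handed to an RBF-kernel SVM, which performs the actual four-class
decision.  The CNN's softmax head is used only to train the feature
extractor.  The network is implemented directly in numpy (two same-padded
convolution blocks with ReLU and max-pooling, a dense layer, Adam on
cross-entropy) and is fully seeded; inputs shorter than the two pooling
stages allow fall back to a dense-only extractor with a logged notice.

Features are standardized with training-split statistics only, and test
metrics never touch training samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .core_io import CLASS_ORDER, FourClassLabel, IntensityMatrix
from .eval_stats import roc_auc
from .split import SplitSpec, stratified_split

__all__ = [
    "CnnConfig",
    "SvmConfig",
    "ClassificationReport",
    "SplitSpec",
    "stratified_split",
    "train_hybrid",
    "classification_report",
    "HybridModel",
]

logger = logging.getLogger(__name__)

MIN_CNN_INPUT = 4  # two pool-by-2 stages need at least 4 positions


@dataclass
class CnnConfig:
    channels: tuple[int, int] = (8, 16)
    kernel_sizes: tuple[int, int] = (7, 5)
    dense_units: int = 32
    epochs: int = 150
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    n_ensemble: int = 3  # independently seeded extractors, activations concatenated
    seed: int = 0


@dataclass
class SvmConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"


# ---------------------------------------------------------------------------
# numpy CNN
# ---------------------------------------------------------------------------


def _conv_forward(A, W, b):
    N, C, L = A.shape
    O, _, K = W.shape
    pad = K // 2
    Ap = np.pad(A, ((0, 0), (0, 0), (pad, pad)))
    out = np.zeros((N, O, L))
    for j in range(K):
        out += np.einsum("ncl,oc->nol", Ap[:, :, j : j + L], W[:, :, j])
    return out + b[None, :, None], Ap


def _conv_backward(dOut, Ap, W):
    N, O, L = dOut.shape
    _, C, K = W.shape
    pad = K // 2
    dW = np.empty_like(W)
    dAp = np.zeros_like(Ap)
    for j in range(K):
        dW[:, :, j] = np.einsum("nol,ncl->oc", dOut, Ap[:, :, j : j + L])
        dAp[:, :, j : j + L] += np.einsum("nol,oc->ncl", dOut, W[:, :, j])
    db = dOut.sum(axis=(0, 2))
    return dAp[:, :, pad : pad + L], dW, db


def _pool_forward(A):
    N, C, L = A.shape
    Lp = L // 2
    A2 = A[:, :, : 2 * Lp].reshape(N, C, Lp, 2)
    idx = A2.argmax(axis=3)
    return A2.max(axis=3), (idx, A.shape)


def _pool_backward(dOut, cache):
    idx, shape = cache
    N, C, L = shape
    Lp = L // 2
    dA2 = np.zeros((N, C, Lp, 2))
    np.put_along_axis(dA2, idx[..., None], dOut[..., None], axis=3)
    dA = np.zeros((N, C, L))
    dA[:, :, : 2 * Lp] = dA2.reshape(N, C, 2 * Lp)
    return dA


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float = 0.0):
        self.lr = lr
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            g = grads[k]
            if self.weight_decay and k.startswith("W"):
                g = g + self.weight_decay * params[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


class Cnn1dFeatures:
    """Two-block 1-D CNN feature extractor trained with a softmax head.

    ``fit`` expects standardized (n_samples, n_features) input and integer
    class labels; ``activations`` returns the penultimate dense-layer output.
    Falls back to a single dense hidden layer when the input is too short to
    pool twice.
    """

    def __init__(self, config: CnnConfig, n_classes: int, input_length: int):
        self.config = config
        self.n_classes = n_classes
        self.input_length = input_length
        self.dense_only = input_length < MIN_CNN_INPUT
        if self.dense_only:
            logger.info(
                "input length %d below the convolutional minimum %d; "
                "using a dense-only feature extractor",
                input_length,
                MIN_CNN_INPUT,
            )
        self.params: dict[str, np.ndarray] = {}
        self._init_params()

    def _init_params(self) -> None:
        rng = np.random.default_rng(self.config.seed)
        c = self.config
        p = self.params
        if self.dense_only:
            flat = self.input_length
        else:
            (c1, c2), (k1, k2) = c.channels, c.kernel_sizes
            p["W1"] = rng.standard_normal((c1, 1, k1)) * np.sqrt(2.0 / k1)
            p["b1"] = np.zeros(c1)
            p["W2"] = rng.standard_normal((c2, c1, k2)) * np.sqrt(2.0 / (c1 * k2))
            p["b2"] = np.zeros(c2)
            l_pool1 = self.input_length // 2
            flat = c2 * (l_pool1 // 2)
        p["Wd"] = rng.standard_normal((flat, c.dense_units)) * np.sqrt(2.0 / flat)
        p["bd"] = np.zeros(c.dense_units)
        p["Wh"] = rng.standard_normal((c.dense_units, self.n_classes)) * np.sqrt(
            2.0 / c.dense_units
        )
        p["bh"] = np.zeros(self.n_classes)

    def _forward(self, X: np.ndarray):
        p = self.params
        cache: dict = {}
        if self.dense_only:
            flat = X
        else:
            A = X[:, None, :]
            Z1, Ap1 = _conv_forward(A, p["W1"], p["b1"])
            R1 = np.maximum(Z1, 0)
            P1, pc1 = _pool_forward(R1)
            Z2, Ap2 = _conv_forward(P1, p["W2"], p["b2"])
            R2 = np.maximum(Z2, 0)
            P2, pc2 = _pool_forward(R2)
            flat = P2.reshape(X.shape[0], -1)
            cache.update(Ap1=Ap1, Z1=Z1, pc1=pc1, Ap2=Ap2, Z2=Z2, pc2=pc2, P2shape=P2.shape)
        Zd = flat @ p["Wd"] + p["bd"]
        Act = np.maximum(Zd, 0)
        logits = Act @ p["Wh"] + p["bh"]
        cache.update(flat=flat, Zd=Zd, Act=Act)
        return logits, cache

    def _backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        p = self.params
        g: dict[str, np.ndarray] = {}
        g["Wh"] = cache["Act"].T @ dlogits
        g["bh"] = dlogits.sum(axis=0)
        dAct = dlogits @ p["Wh"].T
        dZd = dAct * (cache["Zd"] > 0)
        g["Wd"] = cache["flat"].T @ dZd
        g["bd"] = dZd.sum(axis=0)
        if not self.dense_only:
            dflat = dZd @ p["Wd"].T
            dP2 = dflat.reshape(cache["P2shape"])
            dR2 = _pool_backward(dP2, cache["pc2"])
            dZ2 = dR2 * (cache["Z2"] > 0)
            dP1, g["W2"], g["b2"] = _conv_backward(dZ2, cache["Ap2"], p["W2"])
            dR1 = _pool_backward(dP1, cache["pc1"])
            dZ1 = dR1 * (cache["Z1"] > 0)
            _, g["W1"], g["b1"] = _conv_backward(dZ1, cache["Ap1"], p["W1"])
        return g

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Cnn1dFeatures":
        c = self.config
        rng = np.random.default_rng(c.seed + 1)
        opt = _Adam(self.params, c.learning_rate, c.weight_decay)
        n = X.shape[0]
        onehot = np.eye(self.n_classes)[y]
        for _ in range(c.epochs):
            order = rng.permutation(n)
            for start in range(0, n, c.batch_size):
                sel = order[start : start + c.batch_size]
                logits, cache = self._forward(X[sel])
                z = logits - logits.max(axis=1, keepdims=True)
                softmax = np.exp(z)
                softmax /= softmax.sum(axis=1, keepdims=True)
                dlogits = (softmax - onehot[sel]) / len(sel)
                grads = self._backward(dlogits, cache)
                opt.step(self.params, grads)
        return self

    def activations(self, X: np.ndarray) -> np.ndarray:
        _, cache = self._forward(X)
        return cache["Act"]

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(X)
        return logits


# ---------------------------------------------------------------------------
# reports and the hybrid trainer
# ---------------------------------------------------------------------------


@dataclass
class ClassificationReport:
    classes: list
    confusion: np.ndarray  # rows = true, columns = predicted
    per_class_tpr: np.ndarray
    per_class_fnr: np.ndarray
    accuracy: float
    per_class_auc: np.ndarray

    def to_dict(self) -> dict:
        return {
            "classes": [str(getattr(c, "value", c)) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "per_class_tpr": self.per_class_tpr.tolist(),
            "per_class_fnr": self.per_class_fnr.tolist(),
            "accuracy": self.accuracy,
            "per_class_auc": self.per_class_auc.tolist(),
        }


def classification_report(
    true_labels: Sequence,
    predicted_labels: Sequence,
    decision_scores: np.ndarray | None = None,
    classes: Sequence | None = None,
) -> ClassificationReport:
    """Confusion matrix, per-class TPR/FNR, overall accuracy and one-vs-rest
    Mann-Whitney AUC from decision scores (column order = class order)."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels) or not true_labels:
        raise ValueError("aligned non-empty label vectors required")
    if classes is None:
        classes = [c for c in CLASS_ORDER if c in set(true_labels) | set(predicted_labels)]
        if not classes:  # non-enum labels
            classes = sorted(set(true_labels) | set(predicted_labels))
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    for lbl in list(true_labels) + list(predicted_labels):
        if lbl not in index:
            raise ValueError(f"label {lbl!r} outside the class set {classes}")
    k = len(classes)
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        confusion[index[t], index[p]] += 1
    row_sums = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(row_sums > 0, np.diag(confusion) / np.maximum(row_sums, 1), np.nan)
    fnr = 1.0 - tpr
    accuracy = float(np.trace(confusion) / confusion.sum())
    auc = np.full(k, np.nan)
    if decision_scores is not None:
        decision_scores = np.asarray(decision_scores, dtype=float)
        if decision_scores.shape != (len(true_labels), k):
            raise ValueError("decision_scores must be (n_samples, n_classes)")
        y_true = np.array([index[t] for t in true_labels])
        for c in range(k):
            pos = y_true == c
            if pos.any() and (~pos).any():
                auc[c] = roc_auc(decision_scores[:, c], pos).auc
    return ClassificationReport(classes, confusion, tpr, fnr, accuracy, auc)


@dataclass
class HybridModel:
    cnns: list[Cnn1dFeatures]
    svm: SVC
    feature_ids: list[str]
    classes: list[FourClassLabel]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    split: SplitSpec
    calibrated_svm: CalibratedClassifierCV | None = None
    train_report: ClassificationReport | None = None
    test_report: ClassificationReport | None = None

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_sd

    def activations(self, X: np.ndarray) -> np.ndarray:
        Xs = self._prepare(X)
        return np.hstack([cnn.activations(Xs) for cnn in self.cnns])

    def predict(self, X: np.ndarray) -> list[FourClassLabel]:
        return [self.classes[i] for i in self.svm.predict(self.activations(X))]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return self.svm.decision_function(self.activations(X))


def train_hybrid(
    matrix: IntensityMatrix,
    labels: Sequence[FourClassLabel],
    marker_subset: Sequence[str] | None = None,
    split: SplitSpec | None = None,
    cnn_config: CnnConfig | None = None,
    svm_config: SvmConfig | None = None,
    seed: int = 0,
) -> tuple[HybridModel, ClassificationReport]:
    """Train the CNN feature extractor + SVM on the training split and report
    held-out metrics (the primary report; training metrics are kept on the
    model).  Fully deterministic for fixed seeds."""
    matrix.require_log2("train_hybrid")
    if np.isnan(matrix.values).any():
        raise ValueError("train_hybrid needs a complete matrix; run impute_for_ml first")
    labels = [FourClassLabel(l) for l in labels]
    if len(labels) != matrix.n_samples:
        raise ValueError("one label per sample required")
    work = matrix.subset_proteins(marker_subset) if marker_subset else matrix
    if split is None:
        split = stratified_split(matrix.sample_ids, labels, 0.7, seed=seed)
    id_index = {s: i for i, s in enumerate(work.sample_ids)}
    tr = np.array([id_index[s] for s in split.train_ids])
    te = np.array([id_index[s] for s in split.test_ids])
    X = work.values.T
    label_arr = np.array(labels, dtype=object)
    classes = list(CLASS_ORDER)
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[l] for l in labels])

    train_classes = set(label_arr[tr])
    if len(train_classes) < 2:
        only = next(iter(train_classes))
        raise ValueError(
            f"training split contains only class {only.value!r}; cannot fit a classifier"
        )

    mean = X[tr].mean(axis=0)
    sd = X[tr].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd

    cnn_config = cnn_config or CnnConfig(seed=seed)
    svm_config = svm_config or SvmConfig()
    cnns = []
    for e in range(max(1, cnn_config.n_ensemble)):
        member_cfg = replace(cnn_config, seed=cnn_config.seed + 1000 * e)
        cnn = Cnn1dFeatures(member_cfg, n_classes=len(classes), input_length=X.shape[1])
        cnn.fit(Xs[tr], y[tr])
        cnns.append(cnn)

    act_train = np.hstack([c.activations(Xs[tr]) for c in cnns])
    act_test = np.hstack([c.activations(Xs[te]) for c in cnns])
    svm = SVC(
        kernel=svm_config.kernel,
        C=svm_config.C,
        gamma=svm_config.gamma,
        decision_function_shape="ovr",
        random_state=seed,
    )
    svm.fit(act_train, y[tr])

    # Platt-calibrated one-vs-rest class probabilities for ROC scoring; the
    # internal stratified CV is deterministic (no shuffling)
    counts = np.bincount(y[tr], minlength=len(classes))
    cv = int(min(5, counts[counts > 0].min()))
    calibrated = None
    if cv >= 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                calibrated = CalibratedClassifierCV(
                    SVC(
                        kernel=svm_config.kernel,
                        C=svm_config.C,
                        gamma=svm_config.gamma,
                        random_state=seed,
                    ),
                    ensemble=False,
                    cv=cv,
                ).fit(act_train, y[tr])
        except Exception:
            calibrated = None

    def _class_scores(idx, act):
        """Per-class score: mean of calibrated SVM probability and the
        ensemble-average CNN softmax (falls back to the raw ovr decision
        values when calibration is unavailable)."""
        soft = np.zeros((len(idx), len(classes)))
        for cnn in cnns:
            logits = cnn.predict_logits(Xs[idx])
            z = np.exp(logits - logits.max(axis=1, keepdims=True))
            soft += z / z.sum(axis=1, keepdims=True)
        soft /= len(cnns)
        if calibrated is None:
            dec = svm.decision_function(act)
            if dec.ndim == 1:
                dec = np.stack([-dec, dec], axis=1)
            svm_scores = np.full((len(idx), len(classes)), dec.min() - 1.0)
            for col, code in enumerate(svm.classes_):
                svm_scores[:, int(code)] = dec[:, col]
            rng_ = svm_scores.max() - svm_scores.min()
            svm_scores = (svm_scores - svm_scores.min()) / (rng_ if rng_ > 0 else 1.0)
        else:
            prob = calibrated.predict_proba(act)
            svm_scores = np.zeros((len(idx), len(classes)))
            for col, code in enumerate(calibrated.classes_):
                svm_scores[:, int(code)] = prob[:, col]
        return (svm_scores + soft) / 2.0

    def _report(idx, act):
        pred_codes = svm.predict(act)
        return classification_report(
            [labels[i] for i in idx],
            [classes[int(c)] for c in pred_codes],
            _class_scores(idx, act),
            classes=classes,
        )

    model = HybridModel(cnns, svm, list(work.protein_ids), classes, mean, sd, split)
    model.calibrated_svm = calibrated
    model.train_report = _report(tr, act_train)
    model.test_report = _report(te, act_test)
    return model, model.test_report
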