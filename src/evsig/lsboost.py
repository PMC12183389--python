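"""Least-squares boosting and per-biomarker RMSE ranking.

Each biomarker's intensities individually predict a numeric class code via
stage-wise least-squares gradient boosting with depth-1 regression stumps;
the biomarker's held-out RMSE over repeated stratified splits measures how
informative it is (low RMSE = informative).  Aggregate RMSE is min-max
normalized across biomarkers and ranked ascending, and the per-iteration RMSE
vectors of the top markers yield a correlation matrix describing shared
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import CLASS_CODE, FourClassLabel, IntensityMatrix
from .split import stratified_split

__all__ = ["BoostModel", "RmseRanking", "rmse", "fit_lsboost", "rank_biomarkers", "rmse_correlation"]


def rmse(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Root-mean-square error, sqrt(mean((actual - predicted)^2))."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {p.shape}")
    if a.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((a - p) ** 2)))


@dataclass
class BoostModel:
    """A boosted ensemble of depth-1 stumps on a single predictor.

    Prediction is ``base_prediction + learning_rate * sum(stump outputs)``
    where a stump emits ``left_value`` when x <= split_value and
    ``right_value`` otherwise.  Training is fully deterministic given inputs.
    """

    n_learners: int
    learning_rate: float
    base_prediction: float
    stumps: list[tuple[float, float, float]]
    trained_on: str = ""

    def predict(self, x: Sequence[float]) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        pred = np.full(x.shape, self.base_prediction)
        for split, left, right in self.stumps:
            pred += self.learning_rate * np.where(x <= split, left, right)
        return pred

    def staged_train_rmse(self, x: Sequence[float], y: Sequence[float]) -> np.ndarray:
        """Training RMSE after each boosting stage (non-increasing)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        pred = np.full(x.shape, self.base_prediction)
        out = []
        for split, left, right in self.stumps:
            pred += self.learning_rate * np.where(x <= split, left, right)
            out.append(rmse(y, pred))
        return np.array(out)


def _boost_batch(
    X_train: np.ndarray,
    y: np.ndarray,
    X_test: np.ndarray | None,
    n_learners: int,
    learning_rate: float,
):
    """Fit one stump-boosting ensemble per column of ``X_train``, all sharing
    the target ``y``.  Vectorized across columns: each stage sorts residuals
    into each column's x-order once and picks the split maximizing the
    squared-error reduction via prefix sums (ties go to the lowest split
    index).  Columns without any valid split (constant x) contribute the mean
    residual on both sides of a +inf threshold, which keeps training RMSE
    monotone.

    Returns (base, thresholds, left_values, right_values, train_pred, test_pred)
    with per-stage stump parameter arrays of shape (n_learners, n_columns).
    """
    n, m = X_train.shape
    base = float(y.mean())
    order = np.argsort(X_train, axis=0, kind="stable")
    Xs = np.take_along_axis(X_train, order, axis=0)
    valid = Xs[:-1] < Xs[1:]  # (n-1, m)
    candidates = (Xs[:-1] + Xs[1:]) / 2.0
    has_split = valid.any(axis=0)
    n_left = np.arange(1, n, dtype=float)[:, None]
    n_right = n - n_left

    pred = np.full((n, m), base)
    test_pred = None if X_test is None else np.full((X_test.shape[0], m), base)
    thresholds = np.empty((n_learners, m))
    lefts = np.empty((n_learners, m))
    rights = np.empty((n_learners, m))
    cols = np.arange(m)

    for stage in range(n_learners):
        R = y[:, None] - pred
        Rs = np.take_along_axis(R, order, axis=0)
        cs = np.cumsum(Rs, axis=0)
        total = cs[-1]
        left_sum = cs[:-1]
        gain = left_sum**2 / n_left + (total - left_sum) ** 2 / n_right
        gain = np.where(valid, gain, -np.inf)
        best = np.argmax(gain, axis=0)
        thr = candidates[best, cols]
        lv = left_sum[best, cols] / (best + 1)
        rv = (total - left_sum[best, cols]) / (n - best - 1)
        mean_r = total / n
        thr = np.where(has_split, thr, np.inf)
        lv = np.where(has_split, lv, mean_r)
        rv = np.where(has_split, rv, mean_r)
        thresholds[stage] = thr
        lefts[stage] = lv
        rights[stage] = rv
        pred += learning_rate * np.where(X_train <= thr, lv, rv)
        if test_pred is not None:
            test_pred += learning_rate * np.where(X_test <= thr, lv, rv)
    return base, thresholds, lefts, rights, pred, test_pred


def fit_lsboost(
    x: Sequence[float],
    y: Sequence[float],
    n_learners: int = 100,
    learning_rate: float = 0.1,
    seed: int | None = None,
) -> BoostModel:
    """Boost depth-1 stumps on a single predictor.

    ``seed`` is accepted for interface symmetry; the fit itself is
    deterministic (greedy least-squares stumps involve no randomness).
    A constant target yields a model that always predicts the base value.
    """
    if n_learners < 1:
        raise ValueError("n_learners must be >= 1")
    if not 0 < learning_rate <= 1:
        raise ValueError("learning_rate must lie in (0, 1]")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    base, thr, lv, rv, _, _ = _boost_batch(x[:, None], y, None, n_learners, learning_rate)
    stumps = [(float(thr[s, 0]), float(lv[s, 0]), float(rv[s, 0])) for s in range(n_learners)]
    return BoostModel(n_learners, learning_rate, base, stumps, trained_on="x -> y")


@dataclass
class RmseRanking:
    """Per-biomarker held-out RMSE, min-max normalized RMSE and ascending rank,
    plus the full (iterations x biomarkers) RMSE matrix."""

    protein_ids: list[str]
    rmse_values: np.ndarray  # aggregate over iterations, per biomarker
    normalized_rmse: np.ndarray
    rank: np.ndarray  # 1-based, ascending normalized RMSE
    iteration_rmse: np.ndarray  # (n_iterations, n_biomarkers)
    n_iterations: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "protein_id": self.protein_ids,
                "rmse": self.rmse_values,
                "normalized_rmse": self.normalized_rmse,
                "rank": self.rank,
            }
        )
        return df.sort_values("rank").reset_index(drop=True)

    def top(self, k: int) -> list[str]:
        if k > len(self.protein_ids):
            raise ValueError(f"k={k} exceeds {len(self.protein_ids)} biomarkers")
        order = np.argsort(self.rank)
        return [self.protein_ids[i] for i in order[:k]]


def rank_biomarkers(
    matrix: IntensityMatrix,
    labels: Sequence[FourClassLabel],
    k: int = 10,
    n_iterations: int = 50,
    seed: int = 0,
    n_learners: int = 100,
    learning_rate: float = 0.1,
    fraction_train: float = 0.7,
    target: str = "one_vs_rest",
) -> RmseRanking:
    """Rank biomarkers by held-out boosting RMSE against the class target.

    Per iteration a stratified 70/30 split is drawn; each biomarker is fit on
    the training part and its RMSE recorded on the held-out part.
    Aggregation is the mean over iterations.  ``target`` selects the
    regression target: ``'one_vs_rest'`` (default; mean RMSE over the four
    binary class-indicator targets) or ``'ordinal'`` (the numeric class code
    0..3).  One-vs-rest is the default because an ordinal code imposes an
    arbitrary class order and penalizes markers whose profile is high or low
    in non-adjacent classes.  Ties in rank break by protein id.
    """
    matrix.require_log2("rank_biomarkers")
    if np.isnan(matrix.values).any():
        raise ValueError("rank_biomarkers needs a complete matrix; run impute_for_ml first")
    if k > matrix.n_proteins:
        raise ValueError(f"k={k} exceeds the number of proteins ({matrix.n_proteins})")
    labels = [FourClassLabel(l) for l in labels]
    if len(labels) != matrix.n_samples:
        raise ValueError("one label per sample required")
    if len(set(labels)) < 2:
        raise ValueError("at least 2 classes required")
    if target not in ("ordinal", "one_vs_rest"):
        raise ValueError(f"unknown target mode {target!r}")

    X = matrix.values.T  # samples x proteins
    y_code = np.array([CLASS_CODE[l] for l in labels], dtype=float)
    sample_ids = matrix.sample_ids
    id_index = {s: i for i, s in enumerate(sample_ids)}

    iteration_rmse = np.empty((n_iterations, matrix.n_proteins))
    rng = np.random.default_rng(seed)
    for it in range(n_iterations):
        split_seed = int(rng.integers(0, 2**31 - 1))
        split = stratified_split(sample_ids, labels, fraction_train, seed=split_seed)
        tr = np.array([id_index[s] for s in split.train_ids])
        te = np.array([id_index[s] for s in split.test_ids])
        if target == "ordinal":
            _, _, _, _, _, test_pred = _boost_batch(
                X[tr], y_code[tr], X[te], n_learners, learning_rate
            )
            err = np.sqrt(np.mean((y_code[te][:, None] - test_pred) ** 2, axis=0))
        else:
            errs = []
            for code in sorted(set(CLASS_CODE.values())):
                yb = (y_code == code).astype(float)
                _, _, _, _, _, test_pred = _boost_batch(
                    X[tr], yb[tr], X[te], n_learners, learning_rate
                )
                errs.append(np.sqrt(np.mean((yb[te][:, None] - test_pred) ** 2, axis=0)))
            err = np.mean(errs, axis=0)
        iteration_rmse[it] = err

    agg = iteration_rmse.mean(axis=0)
    span = agg.max() - agg.min()
    normalized = (agg - agg.min()) / span if span > 0 else np.zeros_like(agg)
    order = np.lexsort((np.array(matrix.protein_ids), agg))
    rank = np.empty(matrix.n_proteins, dtype=int)
    rank[order] = np.arange(1, matrix.n_proteins + 1)
    return RmseRanking(
        protein_ids=list(matrix.protein_ids),
        rmse_values=agg,
        normalized_rmse=normalized,
        rank=rank,
        iteration_rmse=iteration_rmse,
        n_iterations=n_iterations,
    )


def rmse_correlation(ranking: RmseRanking, top_k: int = 10) -> pd.DataFrame:
    """Pearson correlation between the top-k biomarkers' per-iteration RMSE
    vectors.  Symmetric with unit diagonal; markers whose iteration vector has
    zero variance are listed in ``result.attrs['undefined']`` and their
    off-diagonal entries set to NaN rather than propagating NaN silently."""
    if ranking.n_iterations < 3:
        raise ValueError("need at least 3 iterations for a correlation matrix")
    top = ranking.top(top_k)
    idx = [ranking.protein_ids.index(p) for p in top]
    M = ranking.iteration_rmse[:, idx]
    sd = M.std(axis=0)
    undefined = [top[j] for j in range(len(top)) if sd[j] == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(M, rowvar=False)
    corr = np.atleast_2d(corr)
    for j, pid in enumerate(top):
        if pid in undefined:
            corr[j, :] = np.nan
            corr[:, j] = np.nan
    np.fill_diagonal(corr, 1.0)
    df = pd.DataFrame(corr, index=top, columns=top)
    df.attrs["undefined"] = undefined
    return df
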