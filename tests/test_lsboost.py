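"""Stump boosting, RMSE ranking, and the top-marker correlation matrix."""

import numpy as np
import pytest

from evsig.core_io import CLASS_CODE, FourClassLabel, IntensityMatrix
from evsig.lsboost import (
    RmseRanking,
    fit_lsboost,
    rank_biomarkers,
    rmse,
    rmse_correlation,
)


def test_rmse_values_and_oracle(rng):
    assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
    assert rmse([1, 1, 1], [2, 2, 2]) == 1.0
    a = rng.normal(size=100)
    p = rng.normal(size=100)
    assert rmse(a, p) == pytest.approx(np.sqrt(np.mean((a - p) ** 2)), abs=1e-12)
    with pytest.raises(ValueError):
        rmse([1, 2], [1])
    with pytest.raises(ValueError):
        rmse([], [])


def test_rmse_scale_equivariance(rng):
    a = rng.normal(size=50)
    p = rng.normal(size=50)
    for c in (-3.0, 0.5, 7.0):
        assert rmse(c * a, c * p) == pytest.approx(abs(c) * rmse(a, p), rel=1e-12)


def test_boost_fits_step_function():
    x = np.linspace(0, 1, 40)
    y = (x > 0.5).astype(float) * 2.0
    model = fit_lsboost(x, y, n_learners=200)
    assert rmse(y, model.predict(x)) < 1e-3


def test_boost_training_rmse_monotone(rng):
    x = rng.normal(size=60)
    y = np.sin(3 * x) + rng.normal(0, 0.3, size=60)
    model = fit_lsboost(x, y, n_learners=150)
    staged = model.staged_train_rmse(x, y)
    assert np.all(np.diff(staged) <= 1e-10)


def test_boost_determinism_and_degenerate_cases(rng):
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    m1 = fit_lsboost(x, y, seed=1)
    m2 = fit_lsboost(x, y, seed=99)  # seed is irrelevant: greedy fit
    assert m1.stumps == m2.stumps

    const = fit_lsboost(x, np.full(30, 2.5))
    assert np.allclose(const.predict(x), 2.5)

    flat_x = fit_lsboost(np.full(30, 1.0), y)
    assert np.allclose(flat_x.predict(np.full(5, 1.0)), y.mean())

    with pytest.raises(ValueError):
        fit_lsboost(x, y, n_learners=0)
    with pytest.raises(ValueError):
        fit_lsboost(x[:3], y[:3])


def test_boost_uninformative_predictor(rng):
    # x independent of y: held-out-style training RMSE stays near sd(y)
    floors = []
    for s in range(20):
        r = np.random.default_rng(s)
        x = r.normal(size=80)
        y = r.normal(size=80)
        model = fit_lsboost(x, y)
        floors.append(rmse(y, model.predict(x)) / y.std())
    assert np.mean(floors) > 0.5


def _complete_matrix(rng, n_proteins=30, n_samples=48):
    labels = (
        [FourClassLabel.NORMAL] * 12
        + [FourClassLabel.OTHER_SUBTYPE] * 16
        + [FourClassLabel.TNBC_NO_RECUR] * 12
        + [FourClassLabel.TNBC_RECUR] * 8
    )
    vals = rng.normal(20, 1, size=(n_proteins, n_samples))
    m = IntensityMatrix(
        [f"P{j:02d}" for j in range(n_proteins)],
        [f"S{i:02d}" for i in range(n_samples)],
        vals,
    )
    return m, labels


def test_perfect_predictor_ranks_first(rng):
    m, labels = _complete_matrix(rng)
    codes = np.array([CLASS_CODE[l] for l in labels], dtype=float)
    m.values[0, :] = codes  # biomarker equal to the class code itself
    ranking = rank_biomarkers(m, labels, k=5, n_iterations=10, seed=3)
    assert ranking.top(1) == ["P00"]
    df = ranking.to_frame()
    assert df.iloc[0]["normalized_rmse"] == 0.0
    assert sorted(ranking.rank) == list(range(1, m.n_proteins + 1))


def test_rank_requires_complete_matrix(rng):
    m, labels = _complete_matrix(rng)
    m.values[2, 3] = np.nan
    with pytest.raises(ValueError, match="complete"):
        rank_biomarkers(m, labels, n_iterations=3)
    m2, labels = _complete_matrix(rng)
    with pytest.raises(ValueError, match="k="):
        rank_biomarkers(m2, labels, k=999, n_iterations=3)


def test_rank_deterministic(rng):
    m, labels = _complete_matrix(rng, n_proteins=15)
    r1 = rank_biomarkers(m, labels, n_iterations=5, seed=7, k=5)
    r2 = rank_biomarkers(m, labels, n_iterations=5, seed=7, k=5)
    assert np.array_equal(r1.iteration_rmse, r2.iteration_rmse)
    assert np.array_equal(r1.rank, r2.rank)


def test_rank_invariant_to_monotone_rescaling(rng):
    # ranks depend only on the order of aggregate RMSE
    m, labels = _complete_matrix(rng, n_proteins=12)
    r = rank_biomarkers(m, labels, n_iterations=5, seed=1, k=3)
    order_by_rmse = np.argsort(np.argsort(r.rmse_values, kind="stable"), kind="stable")
    # allow for lexicographic tie-breaks: compare sorted sequences
    assert list(np.sort(r.rank)) == list(range(1, 13))
    assert np.all(r.normalized_rmse[np.argsort(r.rank)][:-1]
                  <= r.normalized_rmse[np.argsort(r.rank)][1:] + 1e-12)


def test_rmse_correlation_properties(rng):
    m, labels = _complete_matrix(rng, n_proteins=12)
    ranking = rank_biomarkers(m, labels, n_iterations=8, seed=2, k=6)
    corr = rmse_correlation(ranking, top_k=6)
    M = corr.to_numpy()
    assert np.allclose(np.diag(M), 1.0)
    assert np.allclose(M, M.T, equal_nan=True)
    assert corr.attrs["undefined"] == []

    # zero-variance iteration vector -> recorded as undefined, no NaN spread
    ranking.iteration_rmse[:, ranking.protein_ids.index(ranking.top(1)[0])] = 1.0
    corr2 = rmse_correlation(ranking, top_k=6)
    assert ranking.top(1) == corr2.attrs["undefined"]
    others = [c for c in corr2.columns if c not in corr2.attrs["undefined"]]
    assert not corr2.loc[others, others].isna().any().any()


def test_null_iteration_vectors_mostly_uncorrelated():
    fracs = []
    for s in range(20):
        r = np.random.default_rng(100 + s)
        fake = RmseRanking(
            protein_ids=[f"P{j}" for j in range(10)],
            rmse_values=np.linspace(0.5, 1.0, 10),
            normalized_rmse=np.linspace(0, 1, 10),
            rank=np.arange(1, 11),
            iteration_rmse=r.normal(1, 0.1, size=(50, 10)),
            n_iterations=50,
        )
        corr = rmse_correlation(fake, top_k=10).to_numpy()
        off = corr[~np.eye(10, dtype=bool)]
        fracs.append(np.mean(np.abs(off) < 0.5))
    assert np.mean(fracs) > 0.95
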