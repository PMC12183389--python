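"""ROC machinery and survival statistics against brute-force oracles."""

import numpy as np
import pytest

from evsig.eval_stats import (
    cox_hazard_ratio,
    km_logrank,
    roc_auc,
    sensitivity_at_fixed_specificity,
)


def _auc_oracle(scores, labels):
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    return sum((p > n) + 0.5 * (p == n) for p in pos for n in neg) / (len(pos) * len(neg))


def test_auc_boundaries_and_oracle(rng):
    s = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
    y = np.array([1, 1, 1, 0, 0])
    assert roc_auc(s, y).auc == 1.0

    tied = roc_auc(np.ones(10), np.array([1] * 4 + [0] * 6))
    assert tied.auc == 0.5

    for _ in range(5):
        s = rng.normal(size=8).round(1)  # force some ties
        y = rng.integers(0, 2, size=8)
        if y.min() == y.max():
            continue
        r = roc_auc(s, y)
        assert r.auc == pytest.approx(_auc_oracle(s, y), abs=1e-12)
        # trapezoidal area of the empirical curve equals Mann-Whitney AUC
        fpr = 1 - r.specificity
        assert np.trapezoid(r.sensitivity, fpr) == pytest.approx(r.auc, abs=1e-12)

    with pytest.raises(ValueError, match="both classes"):
        roc_auc(np.ones(3), np.ones(3))


def test_auc_negation_symmetry(rng):
    s = rng.normal(size=40)
    y = rng.integers(0, 2, size=40)
    assert roc_auc(s, y).auc + roc_auc(-s, y).auc == pytest.approx(1.0, abs=1e-12)


def test_auc_ci_and_se_reasonable(rng):
    s = np.concatenate([rng.normal(1, 1, 50), rng.normal(0, 1, 50)])
    y = np.array([1] * 50 + [0] * 50)
    r = roc_auc(s, y)
    lo, hi = r.ci95
    assert 0 <= lo <= r.auc <= hi <= 1
    assert 0 < r.auc_se < 0.2 and 0 < r.auc_se_delong < 0.2


def test_sensitivity_at_specificity_oracle(rng):
    s = np.array([0.95, 0.9, 0.85, 0.8, 0.7, 0.65, 0.6, 0.5, 0.45, 0.4,
                  0.35, 0.3, 0.28, 0.25, 0.2, 0.15, 0.12, 0.1, 0.05, 0.02])
    y = np.array([1, 1, 0, 1, 1, 1, 0, 1, 0, 1, 0, 0, 1, 0, 0, 1, 0, 0, 0, 0])
    r = roc_auc(s, y)
    sens, ci = sensitivity_at_fixed_specificity(r, 0.8, n_boot=200, seed=1)
    # exhaustive sweep oracle
    pos, neg = s[y == 1], s[y == 0]
    best = 0.0
    for t in np.concatenate([[np.inf], np.unique(s)[::-1]]):
        if (neg < t).mean() >= 0.8:
            best = max(best, (pos >= t).mean())
    assert sens == pytest.approx(best, abs=1e-12)
    assert 0 <= ci[0] <= sens <= ci[1] <= 1


def test_sensitivity_perfect_and_inverted(rng):
    y = np.array([1] * 20 + [0] * 20)
    s = np.concatenate([np.linspace(2, 3, 20), np.linspace(0, 1, 20)])
    r = roc_auc(s, y)
    sens, _ = sensitivity_at_fixed_specificity(r, 0.95, n_boot=100, seed=0)
    assert sens == 1.0
    r_inv = roc_auc(-s, y)
    sens_inv, _ = sensitivity_at_fixed_specificity(r_inv, 0.95, n_boot=100, seed=0)
    assert sens_inv <= 0.05


def _logrank_oracle(times, events, groups):
    """Observed-minus-expected log-rank chi-square, hand computation."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def test_logrank_hand_fixture():
    # 6 subjects, two groups, one censored, no ties
    times = [6, 13, 21, 30, 31, 37]
    events = [1, 1, 1, 1, 0, 1]
    groups = [1, 0, 1, 0, 1, 0]
    res = km_logrank(times, events, groups)
    assert res.logrank_chi2 == pytest.approx(
        _logrank_oracle(times, events, groups), abs=1e-9
    )


def test_logrank_null_and_extreme():
    # identical event data in both groups
    t = [5, 10, 15, 5, 10, 15]
    e = [1, 1, 1, 1, 1, 1]
    g = [0, 0, 0, 1, 1, 1]
    res = km_logrank(t, e, g)
    assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-9)
    assert res.logrank_p == pytest.approx(1.0, abs=1e-9)
    assert res.hazard_ratio == pytest.approx(1.0, abs=1e-9)

    # all events in group 0 strictly before any event in group 1
    t = list(range(1, 11)) + list(range(20, 30))
    e = [1] * 20
    g = [0] * 10 + [1] * 10
    assert km_logrank(t, e, g).logrank_p < 0.01


def test_km_matches_empirical_survival_without_censoring(rng):
    t = rng.exponential(10, size=30).round(2)
    e = np.ones(30, bool)
    g = np.array([0] * 15 + [1] * 15)
    res = km_logrank(t, e, g)
    for lvl in ("0", "1"):
        tt, ss = res.km_curves[lvl]
        sel = g == int(lvl)
        for time, surv in zip(tt, ss):
            emp = (t[sel] > time).mean()
            assert surv == pytest.approx(emp, abs=1e-9)


def test_cox_identity_and_monopolized():
    t = [5, 8, 12, 5, 8, 12]
    e = [1, 1, 0, 1, 1, 0]
    g = [0, 0, 0, 1, 1, 1]
    res = cox_hazard_ratio(t, e, g)
    assert res.converged
    assert res.hazard_ratio == pytest.approx(1.0, abs=1e-6)

    res2 = cox_hazard_ratio([1, 2, 3, 4], [1, 1, 0, 0], [0, 0, 1, 1])
    assert not res2.converged and np.isnan(res2.hazard_ratio)


def test_logrank_and_cox_p_agree(rng):
    t = np.concatenate([rng.exponential(10, 25), rng.exponential(20, 25)]).round(3)
    e = np.ones(50, bool)
    g = np.array([0] * 25 + [1] * 25)
    res = km_logrank(t, e, g)
    # log-rank p and Cox Wald p agree to ~2 decimals on tie-free data
    assert res.logrank_p == pytest.approx(res.hr_p, abs=0.01)
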