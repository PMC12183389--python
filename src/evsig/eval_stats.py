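"""ROC and survival statistics.

AUC is the Mann-Whitney concordance probability with midrank tie handling;
its standard error is reported by the Hanley-McNeil formula and the 95% CI by
the distribution-free DeLong variance (both methods labelled in the result).
Sensitivity at a fixed specificity is read off the empirical ROC curve
conservatively (no interpolation beyond achievable operating points) with a
stratified-bootstrap CI.  Kaplan-Meier curves, the two-sample log-rank test
and Cox proportional-hazards ratios (Efron tie handling) come from lifelines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

__all__ = [
    "RocResult",
    "SurvivalResult",
    "CoxResult",
    "roc_auc",
    "sensitivity_at_fixed_specificity",
    "km_logrank",
    "cox_hazard_ratio",
]

logger = logging.getLogger(__name__)


@dataclass
class RocResult:
    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float  # Hanley-McNeil
    auc_se_delong: float
    ci95: tuple[float, float]  # DeLong
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    m, n = len(pos), len(neg)
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))


def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    m, n = len(pos), len(neg)
    # placement values: midrank concordance of each positive against all
    # negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores: Sequence[float], binary_labels: Sequence) -> RocResult:
    """Empirical ROC with Mann-Whitney AUC, Hanley-McNeil SE and DeLong CI.

    ``binary_labels`` is any 0/1 (or boolean) vector; 1 marks the positive
    class.  Thresholds sweep the observed scores in descending order, with a
    sample called positive when its score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(binary_labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")

    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])

    auc = _mann_whitney_auc(pos, neg)
    m, n = len(pos), len(neg)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    hm_var = (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)) / (m * n)
    se_hm = float(np.sqrt(max(hm_var, 0.0)))
    var_dl = _delong_variance(pos, neg, auc)
    se_dl = float(np.sqrt(max(var_dl, 0.0)))
    z = stats.norm.ppf(0.975)
    ci = (max(0.0, auc - z * se_dl), min(1.0, auc + z * se_dl))
    return RocResult(thresholds, sens, spec, auc, se_hm, se_dl, ci, scores, labels)


def _sens_at_spec(scores: np.ndarray, labels: np.ndarray, target: float) -> float:
    pos = scores[labels]
    neg = scores[~labels]
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    best = None
    for t in thresholds:
        spec = (neg < t).mean()
        if spec >= target:
            s = (pos >= t).mean()
            best = s if best is None else max(best, s)
    return 0.0 if best is None else float(best)


def sensitivity_at_fixed_specificity(
    roc: RocResult,
    target_specificity: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Best achievable sensitivity among operating points with specificity >=
    target, with a stratified-bootstrap percentile CI (resampling positives
    and negatives separately)."""
    if roc.scores is None:
        raise ValueError("RocResult lacks raw scores; rebuild with roc_auc")
    scores, labels = roc.scores, roc.labels
    point = _sens_at_spec(scores, labels, target_specificity)
    if point == 0.0 and not np.any(roc.specificity >= target_specificity):
        logger.info("no threshold attains specificity >= %.3f", target_specificity)
    rng = np.random.default_rng(seed)
    pos = scores[labels]
    neg = scores[~labels]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        p = rng.choice(pos, size=len(pos), replace=True)
        q = rng.choice(neg, size=len(neg), replace=True)
        s = np.concatenate([p, q])
        l = np.concatenate([np.ones(len(p), bool), np.zeros(len(q), bool)])
        boots[b] = _sens_at_spec(s, l, target_specificity)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return point, (float(lo), float(hi))


@dataclass
class CoxResult:
    hazard_ratio: float
    ci95: tuple[float, float]
    p: float
    converged: bool
    note: str = ""


@dataclass
class SurvivalResult:
    km_curves: dict[str, tuple[np.ndarray, np.ndarray]]  # group -> (times, S(t))
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: float
    hr_ci95: tuple[float, float]
    hr_p: float
    cox_converged: bool


def _as_survival_arrays(times, events, groups):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    g = np.asarray(groups)
    if not (len(t) == len(e) == len(g)):
        raise ValueError("times, events and groups must align")
    if (t < 0).any():
        raise ValueError("negative survival time")
    return t, e, g


def cox_hazard_ratio(times, events, group_indicator) -> CoxResult:
    """Two-group Cox proportional-hazards ratio (group=1 vs group=0), Efron
    tie handling, Wald CI on the log scale.  When one group monopolizes the
    events the fit cannot converge; the result is flagged rather than raised."""
    t, e, g = _as_survival_arrays(times, events, group_indicator)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(levels)}")
    ind = (g == levels[1]).astype(float)
    if e.sum() == 0:
        return CoxResult(np.nan, (np.nan, np.nan), np.nan, False, "no events")
    if e[ind == 1].sum() == 0 or e[ind == 0].sum() == 0:
        note = "all events in one group; partial likelihood unbounded"
        return CoxResult(np.nan, (np.nan, np.nan), np.nan, False, note)
    df = pd.DataFrame({"T": t, "E": e.astype(int), "group": ind})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="T", event_col="E")
    except ConvergenceError as err:
        return CoxResult(np.nan, (np.nan, np.nan), np.nan, False, str(err))
    beta = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    z = stats.norm.ppf(0.975)
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - z * se)), float(np.exp(beta + z * se)))
    p = float(cph.summary.loc["group", "p"])
    return CoxResult(hr, ci, p, True)


def km_logrank(times, events, group_indicator) -> SurvivalResult:
    """Kaplan-Meier curves per group plus the two-sample log-rank test and the
    Cox hazard ratio for the same grouping."""
    t, e, g = _as_survival_arrays(times, events, group_indicator)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(levels)}")
    for lvl in levels:
        if (g == lvl).sum() == 0:
            raise ValueError(f"group {lvl} is empty")
    if e.sum() == 0:
        raise ValueError("no events at all; survival comparison undefined")

    curves = {}
    for lvl in levels:
        sel = g == lvl
        km = KaplanMeierFitter()
        km.fit(t[sel], event_observed=e[sel])
        sf = km.survival_function_
        curves[str(lvl)] = (sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy())

    a = g == levels[0]
    lr = logrank_test(t[a], t[~a], event_observed_A=e[a], event_observed_B=e[~a])
    cox = cox_hazard_ratio(t, e, g)
    # identical groups: the statistic is exactly 0 and p exactly 1
    chi2 = float(lr.test_statistic)
    p = float(lr.p_value)
    hr = cox.hazard_ratio
    if not cox.converged:
        hr = np.nan
    elif chi2 < 1e-12 and abs(hr - 1) < 1e-6:
        hr = 1.0
    return SurvivalResult(curves, chi2, p, hr, cox.ci95, cox.p, cox.converged)
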