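"""Multi-marker logistic scoring and combination search.

A marker panel is combined by maximum-likelihood logistic regression into a
probability-scale score in (0, 1) (the tdEV protein score).  Markers whose
Wald p-value exceeds 0.1 are excluded in a single backward pass and the model
refit once on the survivors; overall model fit is summarized by the
likelihood-ratio test.  Exhaustive subset search over a shortlist of
candidates identifies the best combination (highest AUC, then lowest AUC SE,
then fewest markers).  Concentration-scale inputs (immunoassay panels) are
first normalized to the per-marker median of the normal controls; scores
above 0.5 flag high recurrence risk.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from .eval_stats import roc_auc

__all__ = [
    "ScoreModel",
    "CombinationEvaluation",
    "fit_logistic_score",
    "score_samples",
    "evaluate_combinations",
    "normalize_to_control_median",
    "risk_classify",
]

logger = logging.getLogger(__name__)


@dataclass
class ScoreModel:
    markers: list[str]
    intercept: float
    coefficients: dict[str, float]
    excluded: list[tuple[str, float]] = field(default_factory=list)
    alpha: float = 0.05
    lrt_p: float = float("nan")
    separation_flag: bool = False
    scale_branch: str = "log2_intensity"  # or "control_median_ratio"

    def linear_predictor(self, values: pd.DataFrame) -> pd.Series:
        missing = [m for m in self.markers if m not in values.columns]
        if missing:
            raise KeyError(f"marker column(s) missing from input: {missing}")
        lp = pd.Series(self.intercept, index=values.index, dtype=float)
        for m in self.markers:
            lp = lp + self.coefficients[m] * values[m].astype(float)
        return lp


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _ml_fit(X: np.ndarray, y: np.ndarray):
    """statsmodels Logit fit; on separation/divergence returns an L2-penalized
    fallback (flagged), never silent divergence."""
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        separated = not res.mle_retvals.get("converged", False) or np.any(
            np.abs(res.params) > 50
        )
    except Exception:
        res, separated = None, True
    if not separated and res is not None:
        params = np.asarray(res.params, dtype=float)
        pvalues = np.asarray(res.pvalues, dtype=float)
        lrt_p = float(res.llr_pvalue) if X.shape[1] > 0 else float("nan")
        return params, pvalues, lrt_p, False
    clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)  # ridge-penalized
    clf.fit(X, y)
    params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    pvalues = np.full(X.shape[1] + 1, np.nan)  # Wald p undefined under separation
    return params, pvalues, float("nan"), True


def fit_logistic_score(
    values: pd.DataFrame,
    binary_labels: Sequence,
    alpha: float = 0.05,
    exclusion_p: float = 0.1,
    iterate: bool = False,
    scale_branch: str = "log2_intensity",
) -> ScoreModel:
    """Fit the logistic marker-combination model.

    ``values`` is samples x markers (complete); ``binary_labels`` is the
    dichotomous outcome.  Markers with Wald p > ``exclusion_p`` are dropped
    and the model refit once (``iterate=True`` repeats until stable).  Under
    perfect separation the fit falls back to an L2-penalized estimate and the
    model is flagged; no marker is excluded in that case since Wald p-values
    are then undefined.
    """
    y = np.asarray(binary_labels).astype(int)
    if values.isna().any().any():
        raise ValueError("marker values must be complete (no missing entries)")
    if len(values) != len(y):
        raise ValueError("values and labels must align")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    markers = [str(c) for c in values.columns]
    excluded: list[tuple[str, float]] = []

    def fit_current():
        X = values[markers].to_numpy(dtype=float).reshape(len(y), len(markers))
        return _ml_fit(X, y)

    params, pvalues, lrt_p, separated = fit_current()
    while not separated:
        drop = [(m, float(p)) for m, p in zip(markers, pvalues[1:]) if p > exclusion_p]
        if not drop:
            break
        excluded.extend(drop)
        dropped = {d[0] for d in drop}
        markers = [m for m in markers if m not in dropped]
        params, pvalues, lrt_p, separated = fit_current()
        if not iterate or not markers:
            break
    if separated:
        logger.warning("perfect separation detected; penalized fallback used")

    coefficients = {m: float(b) for m, b in zip(markers, params[1:])}
    return ScoreModel(
        markers=markers,
        intercept=float(params[0]),
        coefficients=coefficients,
        excluded=excluded,
        alpha=alpha,
        lrt_p=lrt_p,
        separation_flag=separated,
        scale_branch=scale_branch,
    )


def score_samples(model: ScoreModel, values: pd.DataFrame) -> pd.Series:
    """Probability-scale score in (0, 1): the sigmoid of the linear predictor."""
    return _sigmoid(model.linear_predictor(values)).rename("tdev_protein_score")


@dataclass
class CombinationEvaluation:
    markers: tuple[str, ...]
    auc: float
    auc_se: float
    ci95: tuple[float, float]
    is_best: bool = False


def evaluate_combinations(
    candidate_markers: Sequence[str],
    values: pd.DataFrame,
    binary_labels: Sequence,
    exclusion_p: float | None = None,
    scale_branch: str = "log2_intensity",
) -> list[CombinationEvaluation]:
    """Exhaustive search over all non-empty marker subsets.

    Each subset is fit with :func:`fit_logistic_score`, scored, and its ROC
    AUC with SE computed.  The backward-exclusion rule is off by default
    here: a combination under evaluation is fit as-is, the exclusion rule
    belongs to final model building.  Exactly one evaluation is flagged
    best: highest AUC, ties broken by lowest AUC SE, then by fewer markers,
    then by marker order.  At most 15 candidates (2^15 - 1 subsets) are
    accepted.
    """
    candidates = [str(m) for m in candidate_markers]
    if not candidates:
        raise ValueError("no candidate markers")
    if len(candidates) > 15:
        raise ValueError(
            f"{len(candidates)} candidates is too many for exhaustive search; "
            "shortlist at most 15 (e.g. the top-10 ranked biomarkers)"
        )
    missing = [m for m in candidates if m not in values.columns]
    if missing:
        raise KeyError(f"candidate markers missing from values: {missing}")
    y = np.asarray(binary_labels).astype(int)

    excl = float("inf") if exclusion_p is None else exclusion_p
    evaluations: list[CombinationEvaluation] = []
    for r in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            model = fit_logistic_score(
                values[list(subset)], y, exclusion_p=excl, scale_branch=scale_branch
            )
            scores = score_samples(model, values)
            roc = roc_auc(scores.to_numpy(), y)
            evaluations.append(
                CombinationEvaluation(subset, roc.auc, roc.auc_se, roc.ci95)
            )
    order = {m: i for i, m in enumerate(candidates)}
    best = min(
        range(len(evaluations)),
        key=lambda i: (
            -evaluations[i].auc,
            evaluations[i].auc_se,
            len(evaluations[i].markers),
            tuple(order[m] for m in evaluations[i].markers),
        ),
    )
    evaluations[best].is_best = True
    return evaluations


def normalize_to_control_median(
    concentrations: pd.DataFrame, control_ids: Sequence[str]
) -> pd.DataFrame:
    """Divide each marker column by its median over the normal controls.

    Control medians map to 1 by construction; a value of 3.0 means three
    times the control median.  Non-numeric columns (e.g. a group column) pass
    through unchanged.
    """
    control_ids = [str(c) for c in control_ids]
    missing = [c for c in control_ids if c not in concentrations.index]
    if missing:
        raise KeyError(f"control ids not in table: {missing}")
    if not control_ids:
        raise ValueError("at least one control sample required")
    out = concentrations.copy()
    numeric = out.select_dtypes(include=[np.number]).columns
    for col in numeric:
        ctrl = out.loc[control_ids, col].dropna()
        if ctrl.empty:
            raise ValueError(f"no observed control value for marker {col!r}")
        med = float(ctrl.median())
        if med == 0:
            raise ValueError(f"zero control median for marker {col!r}")
        out[col] = out[col] / med
    return out


def risk_classify(score: float, threshold: float = 0.5) -> str:
    """'high_risk' when score > threshold (strictly), else 'low_risk'."""
    if not 0 <= score <= 1:
        raise ValueError(f"score {score} outside [0, 1]")
    return "high_risk" if score > threshold else "low_risk"
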