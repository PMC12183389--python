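"""Two-group differential expression and the volcano selection rule.

Each protein is tested with a two-sided Welch t-test on observed log2
intensities (pairwise-complete, never imputed); a protein is called
differential when p < 0.05 and |mean log2 difference| > 1, i.e. fold change
greater than 2 on the linear scale.  Raw p-values drive the selection, as in
classical volcano-plot screening; a Benjamini-Hochberg column is emitted for
information only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Group, IntensityMatrix, SampleAnnotation, annotations_for

__all__ = ["VolcanoRow", "two_group_test", "volcano_select", "comparison_grid", "group_selector"]

logger = logging.getLogger(__name__)

Selector = Callable[[SampleAnnotation], bool]


def group_selector(*groups: str | Group) -> Selector:
    """Selector matching any of the given clinical groups."""
    wanted = {Group(g) for g in groups}
    return lambda a: a.group in wanted


@dataclass
class VolcanoRow:
    protein_id: str
    log2_difference: float
    fold_change: float
    p_value: float
    significant_up: bool
    significant_down: bool
    n_a: int
    n_b: int
    q_value: float = float("nan")  # BH-adjusted, informational only


def two_group_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t-test on log2 values.

    Returns ``(p_value, log2_difference)`` with the difference taken as
    mean(a) - mean(b).  Degenerate zero-variance inputs are resolved by the
    mean difference: identical means give p = 1, distinct means p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observed values")
    diff = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return (1.0 if diff == 0 else 0.0), diff
    t = stats.ttest_ind(a, b, equal_var=False)
    return float(t.pvalue), diff


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def volcano_select(
    matrix: IntensityMatrix,
    annotations: Sequence[SampleAnnotation],
    group_a: Selector,
    group_b: Selector,
    p_thresh: float = 0.05,
    fc_log2_thresh: float = 1.0,
) -> list[VolcanoRow]:
    """Volcano screen of group A vs group B over all proteins.

    One row per protein with at least two observed values in each group
    (others are skipped with a logged warning); rows sorted by ascending p.
    Fold change is reported as 2**|log2 difference| with direction carried by
    the up/down flags.
    """
    matrix.require_log2("volcano_select")
    annotations = annotations_for(matrix, annotations)
    idx_a = np.array([i for i, ann in enumerate(annotations) if group_a(ann)], dtype=int)
    idx_b = np.array([i for i, ann in enumerate(annotations) if group_b(ann)], dtype=int)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("both group selectors must match at least one sample")

    rows: list[VolcanoRow] = []
    skipped = []
    for j, pid in enumerate(matrix.protein_ids):
        a = matrix.values[j, idx_a]
        b = matrix.values[j, idx_b]
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            skipped.append(pid)
            continue
        p, diff = two_group_test(a, b)
        rows.append(
            VolcanoRow(
                protein_id=pid,
                log2_difference=diff,
                fold_change=float(2.0 ** abs(diff)),
                p_value=p,
                significant_up=bool(p < p_thresh and diff > fc_log2_thresh),
                significant_down=bool(p < p_thresh and diff < -fc_log2_thresh),
                n_a=int(a.size),
                n_b=int(b.size),
            )
        )
    if skipped:
        logger.warning(
            "volcano_select skipped %d protein(s) with <2 observations per group", len(skipped)
        )
    q = _bh_adjust(np.array([r.p_value for r in rows])) if rows else np.array([])
    for r, qv in zip(rows, q):
        r.q_value = float(qv)
    rows.sort(key=lambda r: (r.p_value, r.protein_id))
    return rows


def volcano_frame(rows: Sequence[VolcanoRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in rows],
            "log2_difference": [r.log2_difference for r in rows],
            "fold_change": [r.fold_change for r in rows],
            "p_value": [r.p_value for r in rows],
            "q_value": [r.q_value for r in rows],
            "significant_up": [r.significant_up for r in rows],
            "significant_down": [r.significant_down for r in rows],
            "n_a": [r.n_a for r in rows],
            "n_b": [r.n_b for r in rows],
        }
    )


def comparison_grid(
    matrix: IntensityMatrix,
    annotations: Sequence[SampleAnnotation],
    comparisons: Sequence[tuple[str, Selector, Selector]],
    marker_subset: Sequence[str] | None = None,
    p_thresh: float = 0.05,
    fc_log2_thresh: float = 1.0,
) -> pd.DataFrame:
    """Effect and p per (comparison x protein): the numbers behind bubble-plot
    style cross-subtype summaries.  Optionally restricted to a marker subset."""
    if not comparisons:
        raise ValueError("comparisons must be non-empty")
    if marker_subset is not None:
        unknown = [m for m in marker_subset if m not in set(matrix.protein_ids)]
        if unknown:
            raise KeyError(f"unknown proteins in marker_subset: {unknown}")
    frames = []
    for name, sel_a, sel_b in comparisons:
        rows = volcano_select(matrix, annotations, sel_a, sel_b, p_thresh, fc_log2_thresh)
        df = volcano_frame(rows)
        if marker_subset is not None:
            df = df[df["protein_id"].isin(set(marker_subset))]
        df.insert(0, "comparison", name)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
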