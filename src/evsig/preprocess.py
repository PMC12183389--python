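"""Normalization and presence filtering.

The identified proteome is reduced to the analysis matrix by two presence
rules: a protein must be observed in at least ``min_n`` individuals of some
group, and (more stringently) in more than a fraction ``min_fraction`` of the
samples of every group.  Differential testing then uses observed values only;
the ML stages receive a median-imputed complete matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import Group, IntensityMatrix, SampleAnnotation, annotations_for

__all__ = [
    "PresenceFilterReport",
    "normalize_intensities",
    "filter_min_individuals",
    "filter_group_presence",
    "impute_for_ml",
]


@dataclass
class PresenceFilterReport:
    """What a presence filter did: counts in/out, the rule applied, and the
    per-group observed counts or fractions for every input protein."""

    n_input: int
    n_output: int
    rule: str
    per_group_presence: dict[str, dict[str, float]] = field(default_factory=dict)
    retained: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for protein, groups in self.per_group_presence.items():
            row = {"protein_id": protein, "retained": protein in set(self.retained)}
            row.update(groups)
            rows.append(row)
        return pd.DataFrame(rows)


def normalize_intensities(matrix: IntensityMatrix) -> IntensityMatrix:
    """log2-transform a linear-scale matrix; the missing mask is unchanged."""
    if matrix.scale_tag != "linear":
        raise ValueError("normalize_intensities expects a linear-scale matrix")
    observed = ~matrix.mask
    bad = observed & (matrix.values <= 0)
    if bad.any():
        j, i = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive intensity at protein {matrix.protein_ids[j]!r}, "
            f"sample {matrix.sample_ids[i]!r}; cannot log2-transform"
        )
    values = np.where(observed, np.log2(np.where(observed, matrix.values, 1.0)), np.nan)
    return IntensityMatrix(list(matrix.protein_ids), list(matrix.sample_ids), values, "log2")


def _group_columns(
    matrix: IntensityMatrix, annotations: Sequence[SampleAnnotation]
) -> dict[str, np.ndarray]:
    annotations = annotations_for(matrix, annotations)
    groups: dict[str, list[int]] = {}
    for i, a in enumerate(annotations):
        groups.setdefault(a.group.value, []).append(i)
    return {g: np.array(cols) for g, cols in groups.items()}


def filter_min_individuals(
    matrix: IntensityMatrix,
    annotations: Sequence[SampleAnnotation],
    min_n: int = 10,
) -> tuple[IntensityMatrix, PresenceFilterReport]:
    """Retain proteins observed in at least ``min_n`` individuals of some group."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    group_cols = _group_columns(matrix, annotations)
    if not group_cols:
        raise ValueError("no groups present")
    observed = ~matrix.mask
    counts = {g: observed[:, cols].sum(axis=1) for g, cols in group_cols.items()}
    keep = np.zeros(matrix.n_proteins, dtype=bool)
    for g in counts:
        keep |= counts[g] >= min_n
    retained = [p for p, k in zip(matrix.protein_ids, keep) if k]
    report = PresenceFilterReport(
        n_input=matrix.n_proteins,
        n_output=len(retained),
        rule=f"observed in >= {min_n} individuals of at least one group",
        per_group_presence={
            p: {g: float(counts[g][j]) for g in counts}
            for j, p in enumerate(matrix.protein_ids)
        },
        retained=retained,
    )
    return matrix.subset_proteins(retained), report


def filter_group_presence(
    matrix: IntensityMatrix,
    annotations: Sequence[SampleAnnotation],
    min_fraction: float = 0.7,
    mode: str = "per_group",
) -> tuple[IntensityMatrix, PresenceFilterReport]:
    """Retain proteins observed in more than ``min_fraction`` of samples.

    ``mode='per_group'`` (default) requires the observed fraction to exceed
    ``min_fraction`` strictly within *every* group; ``mode='fraction_of_groups'``
    is the alternative reading, requiring full presence thresholding in more
    than ``min_fraction`` of the groups (a group counts as present if its
    observed fraction exceeds ``min_fraction``).
    """
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must lie in [0, 1)")
    if mode not in ("per_group", "fraction_of_groups"):
        raise ValueError(f"unknown mode {mode!r}")
    group_cols = _group_columns(matrix, annotations)
    for g, cols in group_cols.items():
        if len(cols) == 0:
            raise ValueError(f"group {g} is empty")
    observed = ~matrix.mask
    fractions = {
        g: observed[:, cols].sum(axis=1) / len(cols) for g, cols in group_cols.items()
    }
    frac_matrix = np.stack([fractions[g] for g in fractions], axis=1)
    if mode == "per_group":
        keep = (frac_matrix > min_fraction).all(axis=1)
    else:
        keep = (frac_matrix > min_fraction).mean(axis=1) > min_fraction
    retained = [p for p, k in zip(matrix.protein_ids, keep) if k]
    report = PresenceFilterReport(
        n_input=matrix.n_proteins,
        n_output=len(retained),
        rule=f"observed fraction > {min_fraction} ({mode})",
        per_group_presence={
            p: {g: float(fractions[g][j]) for g in fractions}
            for j, p in enumerate(matrix.protein_ids)
        },
        retained=retained,
    )
    return matrix.subset_proteins(retained), report


def impute_for_ml(matrix: IntensityMatrix) -> IntensityMatrix:
    """Replace each missing entry by its protein's median observed value.

    Imputation is per protein over all samples (never per group, which would
    leak class labels into the classifier input).  The input matrix is left
    untouched.  A protein with no observed value at all cannot be imputed and
    is an error; the group-presence filter guarantees this cannot happen
    downstream of preprocessing.
    """
    values = matrix.values.copy()
    mask = matrix.mask
    if not mask.any():
        return matrix.copy()
    n_obs = (~mask).sum(axis=1)
    if (n_obs == 0).any():
        j = int(np.argwhere(n_obs == 0)[0][0])
        raise ValueError(f"protein {matrix.protein_ids[j]!r} has no observed values")
    medians = np.nanmedian(values, axis=1)
    rows, cols = np.where(mask)
    values[rows, cols] = medians[rows]
    return IntensityMatrix(list(matrix.protein_ids), list(matrix.sample_ids), values, matrix.scale_tag)
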