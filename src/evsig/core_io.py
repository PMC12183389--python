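"""Core data model and file I/O for the tdEV proteome pipeline.

The central object is :class:`IntensityMatrix`, a proteins x samples array of
log2 TMT reporter intensities with explicit missingness, accompanied by one
:class:`SampleAnnotation` per sample (clinical group, recurrence status, and
optional survival follow-up).  Classification stages operate on the four-class
target derived by :func:`derive_four_class_label`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Recurrence",
    "FourClassLabel",
    "IntensityMatrix",
    "SampleAnnotation",
    "derive_four_class_label",
    "load_dataset",
    "write_dataset",
    "load_matrix",
    "write_matrix",
    "load_annotations",
    "write_annotations",
]

#: Tokens accepted as "missing" in delimited files (written back as empty).
MISSING_TOKENS = {"", "NA", "nan", "NaN"}

#: Covariate columns recognised in annotation tables beyond the core fields.
COVARIATE_COLUMNS = ("age", "stage", "ki67", "ca15_3", "cea")


class Group(str, Enum):
    HC = "HC"
    LUMINAL = "Luminal"
    HER2 = "HER2"
    TNBC = "TNBC"


class Recurrence(str, Enum):
    NONE = "none"
    EARLY = "early"  # before 2 years
    LATE = "late"  # within 2-5 years
    NOT_APPLICABLE = "not_applicable"


class FourClassLabel(str, Enum):
    NORMAL = "Normal"
    OTHER_SUBTYPE = "OtherSubtype"
    TNBC_NO_RECUR = "TNBC_no_recur"
    TNBC_RECUR = "TNBC_recur"


#: Numeric class codes used as the regression target in the boosting stage.
CLASS_CODE = {
    FourClassLabel.NORMAL: 0,
    FourClassLabel.OTHER_SUBTYPE: 1,
    FourClassLabel.TNBC_NO_RECUR: 2,
    FourClassLabel.TNBC_RECUR: 3,
}

#: Stable class ordering used by classifiers and reports.
CLASS_ORDER = (
    FourClassLabel.NORMAL,
    FourClassLabel.OTHER_SUBTYPE,
    FourClassLabel.TNBC_NO_RECUR,
    FourClassLabel.TNBC_RECUR,
)


@dataclass
class IntensityMatrix:
    """Proteins x samples intensity matrix with explicit missingness.

    Missing entries are stored as ``numpy.nan`` in :attr:`values`; the boolean
    :attr:`mask` property exposes them explicitly.  A missing value is never
    represented as zero.  ``scale_tag`` records whether values are raw linear
    reporter intensities or log2-transformed; differential-expression and ML
    stages require ``log2``.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale_tag: str = "log2"

    def __post_init__(self) -> None:
        self.protein_ids = [str(p) for p in self.protein_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (proteins x samples)")
        if self.values.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.sample_ids)} samples"
            )
        if len(set(self.protein_ids)) != len(self.protein_ids):
            dupes = sorted({p for p in self.protein_ids if self.protein_ids.count(p) > 1})
            raise ValueError(f"duplicate protein ids: {dupes}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.scale_tag not in ("log2", "linear"):
            raise ValueError(f"scale_tag must be 'log2' or 'linear', got {self.scale_tag!r}")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the entry is missing."""
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.sample_ids)

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            list(self.protein_ids), list(self.sample_ids), self.values.copy(), self.scale_tag
        )

    def subset_proteins(self, protein_ids: Sequence[str]) -> "IntensityMatrix":
        index = {p: i for i, p in enumerate(self.protein_ids)}
        missing = [p for p in protein_ids if p not in index]
        if missing:
            raise KeyError(f"unknown protein ids: {missing}")
        rows = [index[p] for p in protein_ids]
        return IntensityMatrix(
            list(protein_ids), list(self.sample_ids), self.values[rows, :].copy(), self.scale_tag
        )

    def require_log2(self, stage: str) -> None:
        if self.scale_tag != "log2":
            raise ValueError(
                f"{stage} requires a log2-scale matrix; call normalize_intensities first"
            )


def _absent(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class SampleAnnotation:
    """Clinical annotation for one sample.

    Healthy controls carry ``recurrence == not_applicable`` and no survival
    fields.  Recurrence timing distinguishes early (before 2 years) from late
    (within 2-5 years) events; classification collapses both into a single
    recurrent class while survival analysis keeps the timing.
    """

    sample_id: str
    group: Group
    recurrence: Recurrence
    rfs_time: float | None = None
    rfs_event: bool | None = None
    os_time: float | None = None
    os_event: bool | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.recurrence = Recurrence(self.recurrence)
        if self.group == Group.HC:
            if self.recurrence != Recurrence.NOT_APPLICABLE:
                raise ValueError(
                    f"sample {self.sample_id}: healthy control must have "
                    "recurrence == not_applicable"
                )
            if not (_absent(self.rfs_time) and _absent(self.os_time)):
                raise ValueError(
                    f"sample {self.sample_id}: healthy control must not carry survival times"
                )
        else:
            if self.recurrence == Recurrence.NOT_APPLICABLE:
                raise ValueError(
                    f"sample {self.sample_id}: patient sample needs a recurrence "
                    "status (none/early/late)"
                )
        for t in (self.rfs_time, self.os_time):
            if not _absent(t) and t < 0:
                raise ValueError(f"sample {self.sample_id}: negative survival time")
        if not _absent(self.rfs_time) and not _absent(self.os_time):
            if self.rfs_time > self.os_time + 1e-9:
                raise ValueError(
                    f"sample {self.sample_id}: rfs_time {self.rfs_time} exceeds "
                    f"os_time {self.os_time}"
                )

    @property
    def has_survival(self) -> bool:
        return not _absent(self.rfs_time) and not _absent(self.os_time)


def derive_four_class_label(annotation: SampleAnnotation) -> FourClassLabel:
    """Map a clinical annotation onto the four-class classification target.

    Healthy controls map to Normal; TNBC patients split by recurrence status
    (early and late recurrence are collapsed into one recurrent class);
    Luminal and HER2 patients form the other-subtypes class regardless of
    recurrence.
    """
    if annotation.group == Group.HC:
        return FourClassLabel.NORMAL
    if annotation.group == Group.TNBC:
        if annotation.recurrence in (Recurrence.EARLY, Recurrence.LATE):
            return FourClassLabel.TNBC_RECUR
        return FourClassLabel.TNBC_NO_RECUR
    return FourClassLabel.OTHER_SUBTYPE


def derive_labels(annotations: Iterable[SampleAnnotation]) -> list[FourClassLabel]:
    return [derive_four_class_label(a) for a in annotations]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def load_matrix(path: str | Path, scale_tag: str = "log2") -> IntensityMatrix:
    """Read a delimited intensity matrix (first column protein id, header row
    sample ids).  Empty cells and the literal ``NA`` parse as missing; any
    other non-numeric cell is an error naming the offending protein and
    sample."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a protein-id column plus sample columns")
    protein_ids = [str(p) for p in df.iloc[:, 0]]
    sample_ids = [str(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:].to_numpy(dtype=object)
    values = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell in MISSING_TOKENS:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at protein "
                        f"{protein_ids[i]!r}, sample {sample_ids[j]!r}"
                    ) from None
    return IntensityMatrix(protein_ids, sample_ids, values, scale_tag)


def write_matrix(matrix: IntensityMatrix, path: str | Path) -> None:
    path = Path(path)
    df = matrix.to_frame()
    df.index.name = "protein_id"
    df.to_csv(path, sep=_sep_for(path), na_rep="")


def _parse_bool(cell: str) -> bool | None:
    cell = cell.strip()
    if cell in MISSING_TOKENS:
        return None
    if cell.lower() in ("true", "1", "yes"):
        return True
    if cell.lower() in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean value {cell!r}")


def _parse_float(cell: str) -> float | None:
    cell = cell.strip()
    if cell in MISSING_TOKENS:
        return None
    return float(cell)


def load_annotations(path: str | Path) -> list[SampleAnnotation]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    required = {"sample_id", "group", "recurrence"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: annotation table missing columns {sorted(missing_cols)}")
    extra = [c for c in df.columns if c in COVARIATE_COLUMNS]
    annotations = []
    for _, row in df.iterrows():
        covariates = {c: row[c] for c in extra if str(row[c]).strip() not in MISSING_TOKENS}
        annotations.append(
            SampleAnnotation(
                sample_id=str(row["sample_id"]),
                group=Group(row["group"]),
                recurrence=Recurrence(row["recurrence"]),
                rfs_time=_parse_float(row.get("rfs_time", "")),
                rfs_event=_parse_bool(row.get("rfs_event", "")),
                os_time=_parse_float(row.get("os_time", "")),
                os_event=_parse_bool(row.get("os_event", "")),
                covariates=covariates,
            )
        )
    ids = [a.sample_id for a in annotations]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample ids in annotation table")
    return annotations


def annotations_to_frame(annotations: Sequence[SampleAnnotation]) -> pd.DataFrame:
    covariate_keys: list[str] = []
    for a in annotations:
        for k in a.covariates:
            if k not in covariate_keys:
                covariate_keys.append(k)
    rows = []
    for a in annotations:
        row = {
            "sample_id": a.sample_id,
            "group": a.group.value,
            "recurrence": a.recurrence.value,
            "rfs_time": a.rfs_time,
            "rfs_event": a.rfs_event,
            "os_time": a.os_time,
            "os_event": a.os_event,
        }
        for k in covariate_keys:
            row[k] = a.covariates.get(k)
        rows.append(row)
    return pd.DataFrame(rows)


def write_annotations(annotations: Sequence[SampleAnnotation], path: str | Path) -> None:
    path = Path(path)
    annotations_to_frame(annotations).to_csv(path, sep=_sep_for(path), index=False, na_rep="")


def load_dataset(
    matrix_path: str | Path,
    annotation_path: str | Path,
    scale_tag: str = "log2",
) -> tuple[IntensityMatrix, list[SampleAnnotation]]:
    """Load matrix and annotations and align them.

    Every matrix column must have exactly one annotation; annotations are
    returned in matrix column order.  If the annotation ids instead match the
    matrix *rows*, the matrix is transposed relative to the expected
    proteins-in-rows orientation and loading fails rather than guessing.
    """
    matrix = load_matrix(matrix_path, scale_tag=scale_tag)
    annotations = load_annotations(annotation_path)
    by_id = {a.sample_id: a for a in annotations}
    unmatched = [s for s in matrix.sample_ids if s not in by_id]
    if unmatched:
        row_hits = sum(1 for p in matrix.protein_ids if p in by_id)
        if row_hits > len(matrix.protein_ids) / 2:
            raise ValueError(
                "annotation sample ids match matrix rows, not columns: the matrix "
                "appears transposed (expected proteins in rows, samples in columns)"
            )
        raise ValueError(f"matrix samples without annotation: {unmatched}")
    return matrix, [by_id[s] for s in matrix.sample_ids]


def write_dataset(
    matrix: IntensityMatrix,
    annotations: Sequence[SampleAnnotation],
    matrix_path: str | Path,
    annotation_path: str | Path,
) -> None:
    write_matrix(matrix, matrix_path)
    write_annotations(annotations, annotation_path)


def annotations_for(
    matrix: IntensityMatrix, annotations: Sequence[SampleAnnotation]
) -> list[SampleAnnotation]:
    """Annotations reordered to match the matrix columns."""
    by_id = {a.sample_id: a for a in annotations}
    missing = [s for s in matrix.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"matrix samples without annotation: {missing}")
    return [by_id[s] for s in matrix.sample_ids]
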