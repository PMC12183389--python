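"""Presence filters, log2 normalization and median imputation."""

import numpy as np
import pytest

from evsig.core_io import Group, IntensityMatrix, Recurrence, SampleAnnotation
from evsig.preprocess import (
    filter_group_presence,
    filter_min_individuals,
    impute_for_ml,
    normalize_intensities,
)


def _annotations(groups):
    out = []
    for i, g in enumerate(groups):
        rec = Recurrence.NOT_APPLICABLE if g == Group.HC else Recurrence.NONE
        out.append(SampleAnnotation(f"S{i:03d}", g, rec))
    return out


def _matrix(values, scale="log2"):
    values = np.asarray(values, dtype=float)
    return IntensityMatrix(
        [f"P{j}" for j in range(values.shape[0])],
        [f"S{i:03d}" for i in range(values.shape[1])],
        values,
        scale,
    )


def test_normalize_exact_points_and_oracle(rng):
    m = _matrix([[8.0, 1.0, 4.0]], scale="linear")
    out = normalize_intensities(m)
    assert out.values.tolist() == [[3.0, 0.0, 2.0]]
    assert out.scale_tag == "log2"

    vals = rng.uniform(0.1, 1e6, size=(30, 8))
    vals[rng.random((30, 8)) < 0.2] = np.nan
    m = _matrix(vals, scale="linear")
    out = normalize_intensities(m)
    obs = ~np.isnan(vals)
    assert np.allclose(out.values[obs], np.log2(vals[obs]), atol=1e-12)
    assert np.array_equal(np.isnan(out.values), ~obs)


def test_normalize_rejects_bad_input():
    m = _matrix([[2.0, -1.0]], scale="linear")
    with pytest.raises(ValueError, match="P0"):
        normalize_intensities(m)
    with pytest.raises(ValueError, match="linear"):
        normalize_intensities(_matrix([[1.0]], scale="log2"))


def test_min_individuals_boundary():
    # protein observed in exactly 10 HC, nowhere else -> retained at min_n=10
    groups = [Group.HC] * 12 + [Group.TNBC] * 12
    ann = _annotations(groups)
    values = np.full((2, 24), np.nan)
    values[0, :10] = 5.0  # 10 HC observations
    values[1, :9] = 5.0  # 9 observations everywhere -> dropped
    values[1, 12:21] = 5.0  # 9 TNBC observations
    m = _matrix(values)
    kept, report = filter_min_individuals(m, ann, min_n=10)
    assert kept.protein_ids == ["P0"]
    assert report.n_input == 2 and report.n_output == 1


def test_min_individuals_brute_force(rng):
    groups = [Group.HC] * 8 + [Group.LUMINAL] * 6 + [Group.TNBC] * 7
    ann = _annotations(groups)
    vals = rng.normal(size=(25, 21))
    vals[rng.random((25, 21)) < 0.5] = np.nan
    m = _matrix(vals)
    kept, _ = filter_min_individuals(m, ann, min_n=4)
    expected = []
    spans = {"HC": range(0, 8), "Luminal": range(8, 14), "TNBC": range(14, 21)}
    for j in range(25):
        counts = [sum(not np.isnan(vals[j, i]) for i in span) for span in spans.values()]
        if any(c >= 4 for c in counts):
            expected.append(f"P{j}")
    assert kept.protein_ids == expected


def test_group_presence_strict_boundary():
    # 10 samples per group: 8/10 = 80% retained, exactly 7/10 = 70% dropped
    groups = [Group.HC] * 10 + [Group.TNBC] * 10
    ann = _annotations(groups)
    values = np.full((2, 20), 1.0)
    values[0, 8:10] = np.nan  # HC presence 80%
    values[1, 7:10] = np.nan  # HC presence exactly 70% -> strict rule drops
    m = _matrix(values)
    kept, report = filter_group_presence(m, ann, min_fraction=0.7)
    assert kept.protein_ids == ["P0"]
    assert report.per_group_presence["P1"]["HC"] == pytest.approx(0.7)


def test_group_presence_brute_force_and_idempotence(rng):
    groups = [Group.HC] * 9 + [Group.HER2] * 11
    ann = _annotations(groups)
    vals = rng.normal(size=(40, 20))
    vals[rng.random((40, 20)) < 0.35] = np.nan
    m = _matrix(vals)
    kept, _ = filter_group_presence(m, ann, min_fraction=0.6)
    expected = []
    for j in range(40):
        f_hc = np.mean(~np.isnan(vals[j, :9]))
        f_h2 = np.mean(~np.isnan(vals[j, 9:]))
        if f_hc > 0.6 and f_h2 > 0.6:
            expected.append(f"P{j}")
    assert kept.protein_ids == expected
    again, _ = filter_group_presence(kept, ann, min_fraction=0.6)
    assert again.protein_ids == kept.protein_ids
    assert np.array_equal(again.values, kept.values, equal_nan=True)


def test_filters_monotone_in_threshold(rng):
    groups = [Group.HC] * 10 + [Group.TNBC] * 10
    ann = _annotations(groups)
    vals = rng.normal(size=(30, 20))
    vals[rng.random((30, 20)) < 0.4] = np.nan
    m = _matrix(vals)
    prev = None
    for frac in (0.8, 0.6, 0.4, 0.2):
        kept, _ = filter_group_presence(m, ann, min_fraction=frac)
        if prev is not None:
            assert set(prev) <= set(kept.protein_ids)
        prev = kept.protein_ids
    prev = None
    for n in (9, 6, 3, 1):
        kept, _ = filter_min_individuals(m, ann, min_n=n)
        if prev is not None:
            assert set(prev) <= set(kept.protein_ids)
        prev = kept.protein_ids


def test_impute_median(rng):
    m = _matrix([[1.0, 3.0, np.nan]])
    out = impute_for_ml(m)
    assert out.values.tolist() == [[1.0, 3.0, 2.0]]
    assert np.isnan(m.values[0, 2])  # original untouched

    complete = _matrix(rng.normal(size=(5, 6)))
    assert np.array_equal(impute_for_ml(complete).values, complete.values)

    vals = rng.normal(size=(15, 12))
    vals[rng.random((15, 12)) < 0.3] = np.nan
    m = _matrix(vals)
    out = impute_for_ml(m)
    for j in range(15):
        med = np.nanmedian(vals[j])
        missing = np.isnan(vals[j])
        assert np.allclose(out.values[j, missing], med)
        assert np.allclose(out.values[j, ~missing], vals[j, ~missing])

    with pytest.raises(ValueError, match="no observed"):
        impute_for_ml(_matrix([[np.nan, np.nan]]))
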