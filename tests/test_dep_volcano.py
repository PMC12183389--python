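"""Welch testing and the volcano selection rule."""

import math

import numpy as np
import pytest
from scipy import stats

from evsig.core_io import Group, IntensityMatrix, Recurrence, SampleAnnotation
from evsig.dep_volcano import comparison_grid, group_selector, two_group_test, volcano_select
from evsig.panels import dep_rule, discovery_panel


def _welch_oracle(a, b):
    """Textbook Welch t: statistic, Satterthwaite df, two-sided p."""
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * stats.t.sf(abs(t), df)


def test_two_group_identical_and_shift(rng):
    a = rng.normal(size=12)
    p, diff = two_group_test(a, a.copy())
    assert diff == 0 and abs(p - 1.0) < 1e-9

    b = rng.normal(size=20)
    p, diff = two_group_test(b + 1.0, b)
    assert diff == pytest.approx(1.0, abs=1e-12)
    assert p < 0.05


def test_two_group_welch_oracle(rng):
    for _ in range(10):
        a = rng.normal(0, 1.3, size=rng.integers(5, 30))
        b = rng.normal(0.4, 0.7, size=rng.integers(5, 30))
        p, diff = two_group_test(a, b)
        assert p == pytest.approx(_welch_oracle(a, b), abs=1e-10)
        assert diff == pytest.approx(a.mean() - b.mean(), abs=1e-12)
    with pytest.raises(ValueError):
        two_group_test([1.0], [1.0, 2.0])


def _toy_dataset(rng, shifts):
    n_hc, n_tnbc = 12, 14
    ann = [
        SampleAnnotation(f"S{i:02d}", Group.HC, Recurrence.NOT_APPLICABLE)
        for i in range(n_hc)
    ] + [
        SampleAnnotation(f"S{i + n_hc:02d}", Group.TNBC, Recurrence.NONE)
        for i in range(n_tnbc)
    ]
    vals = rng.normal(20, 0.5, size=(len(shifts), n_hc + n_tnbc))
    for j, s in enumerate(shifts):
        vals[j, n_hc:] += s
    m = IntensityMatrix([f"P{j}" for j in range(len(shifts))], [a.sample_id for a in ann], vals)
    return m, ann


def test_volcano_flags_match_brute_force(rng):
    shifts = [0.0, 0.3, 1.5, -1.5, 2.5, 0.0, 1.2, -0.4, 3.0, 0.9] * 2
    m, ann = _toy_dataset(rng, shifts)
    rows = volcano_select(m, ann, group_selector(Group.TNBC), group_selector(Group.HC))
    assert [r.p_value for r in rows] == sorted(r.p_value for r in rows)
    by_id = {r.protein_id: r for r in rows}
    for j, pid in enumerate(m.protein_ids):
        a = m.values[j, 12:]
        b = m.values[j, :12]
        p = _welch_oracle(a, b)
        d = a.mean() - b.mean()
        r = by_id[pid]
        assert r.significant_up == (p < 0.05 and d > 1.0)
        assert r.significant_down == (p < 0.05 and d < -1.0)
        assert not (r.significant_up and r.significant_down)
        assert r.fold_change == pytest.approx(2 ** abs(d))


def test_volcano_swap_symmetry(rng):
    m, ann = _toy_dataset(rng, [0.0, 1.4, -1.2, 0.6])
    fwd = volcano_select(m, ann, group_selector(Group.TNBC), group_selector(Group.HC))
    rev = volcano_select(m, ann, group_selector(Group.HC), group_selector(Group.TNBC))
    f = {r.protein_id: r for r in fwd}
    r_ = {r.protein_id: r for r in rev}
    for pid in f:
        assert f[pid].log2_difference == pytest.approx(-r_[pid].log2_difference)
        assert f[pid].p_value == pytest.approx(r_[pid].p_value, abs=1e-12)
        assert f[pid].significant_up == r_[pid].significant_down
        assert f[pid].significant_down == r_[pid].significant_up


def test_volcano_threshold_monotonicity(rng):
    m, ann = _toy_dataset(rng, [0.0, 0.5, 1.1, 1.8, -2.0, 0.9])
    def flagged(p_thresh, fc_thresh):
        rows = volcano_select(
            m, ann, group_selector(Group.TNBC), group_selector(Group.HC),
            p_thresh=p_thresh, fc_log2_thresh=fc_thresh,
        )
        return {r.protein_id for r in rows if r.significant_up or r.significant_down}
    base = flagged(0.05, 1.0)
    assert flagged(0.01, 1.0) <= base
    assert flagged(0.05, 1.5) <= base


def test_comparison_grid_consistency(rng):
    m, ann = _toy_dataset(rng, [0.0, 1.6, 2.2, -0.2])
    grid = comparison_grid(
        m, ann, [("tnbc_vs_hc", group_selector(Group.TNBC), group_selector(Group.HC))],
        marker_subset=["P1", "P2"],
    )
    assert set(grid["protein_id"]) == {"P1", "P2"}
    rows = volcano_select(m, ann, group_selector(Group.TNBC), group_selector(Group.HC))
    sub = {r.protein_id: r for r in rows if r.protein_id in ("P1", "P2")}
    for _, g in grid.iterrows():
        assert g["p_value"] == pytest.approx(sub[g["protein_id"]].p_value)
    with pytest.raises(KeyError, match="NOPE"):
        comparison_grid(
            m, ann, [("c", group_selector(Group.TNBC), group_selector(Group.HC))],
            marker_subset=["NOPE"],
        )
    with pytest.raises(ValueError):
        comparison_grid(m, ann, [])


def test_discovery_panel_passes_dep_rule():
    panel = discovery_panel()
    assert len(panel) == 26
    keep = dep_rule(panel["p_value"], panel["fold_change"])
    assert keep.all()
    # the rule is strict: values at the thresholds fail
    assert not dep_rule([0.05], [3.0])[0]
    assert not dep_rule([0.01], [2.0])[0]
    row = panel.set_index("gene").loc["MBL2"]
    assert dep_rule([row["p_value"]], [row["fold_change"]])[0]
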