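import numpy as np
import pytest
from scipy import stats

from _oracles import mwu_exact_bruteforce
from hydroprofiler.profile import (
    PSEUDO_VALUE_HUMAN,
    PSEUDO_VALUE_MURINE,
    aggregate_categories,
    bonferroni_adjust,
    build_hit_table,
    compare_groups,
    comparison_frame,
    mann_whitney_u,
    normalize_hit_table,
    per_entry_group_averages,
)


@pytest.fixture()
def table(tiny_db):
    counts = {
        "s1": {"uptake_01": 8, "evolving_01": 2},
        "s2": {"uptake_01": 6, "evolving_01": 4},
        "s3": {"uptake_01": 1, "evolving_01": 9},
        "s4": {},  # no mapped reads at all
    }
    groups = {"s1": "a", "s2": "a", "s3": "b", "s4": "b"}
    return build_hit_table(counts, groups, entry_ids=tiny_db.active_ids)


def test_build_hit_table_structural_zeros(table, tiny_db):
    assert list(table.counts.columns) == sorted(tiny_db.active_ids)
    assert table.counts.loc["s1", "sensory_01"] == 0
    assert (table.counts.loc["s4"] == 0).all()
    with pytest.raises(ValueError, match="without a group"):
        build_hit_table({"sX": {}}, {})
    with pytest.raises(ValueError, match="unknown entries"):
        build_hit_table({"s1": {"bogus": 1}}, {"s1": "a"}, entry_ids=["e1"])


def test_normalize_rows_sum_to_one(table):
    norm = normalize_hit_table(table)
    sums = norm.fractions.sum(axis=1)
    assert sums.loc["s1"] == pytest.approx(1.0)
    assert sums.loc["s4"] == 0.0
    assert norm.zero_samples == ("s4",)
    assert norm.totals.loc["s2"] == 10


def test_normalization_depth_invariance(table, tiny_db):
    norm1 = normalize_hit_table(table)
    scaled = build_hit_table(
        {s: {e: 7 * c for e, c in row.items()} for s, row in {
            "s1": {"uptake_01": 8, "evolving_01": 2},
            "s2": {"uptake_01": 6, "evolving_01": 4},
            "s3": {"uptake_01": 1, "evolving_01": 9},
            "s4": {},
        }.items()},
        {"s1": "a", "s2": "a", "s3": "b", "s4": "b"},
        entry_ids=tiny_db.active_ids,
    )
    norm2 = normalize_hit_table(scaled)
    assert np.allclose(norm1.fractions, norm2.fractions)


def test_aggregate_categories(table, tiny_db):
    norm = normalize_hit_table(table)
    prof = aggregate_categories(norm, tiny_db)
    assert list(prof.abundances.columns) == [
        "uptake", "evolving", "bidirectional", "bifurcating", "sensory",
    ]
    assert prof.abundances.loc["s1", "uptake"] == pytest.approx(0.8)
    assert prof.abundances.loc["s3", "evolving"] == pytest.approx(0.9)


def test_pseudo_value_substitution_after_averaging(table):
    norm = normalize_hit_table(table)
    avgs = per_entry_group_averages(norm, pseudo_value=PSEUDO_VALUE_MURINE)
    # sensory_01 never recruits -> group means exactly 0 -> pseudo-value
    assert avgs["a"]["sensory_01"] == PSEUDO_VALUE_MURINE
    assert avgs["b"]["sensory_01"] == PSEUDO_VALUE_MURINE
    # non-zero means are untouched
    assert avgs["a"]["uptake_01"] == pytest.approx((0.8 + 0.6) / 2)
    assert PSEUDO_VALUE_HUMAN == 0.0005 and PSEUDO_VALUE_MURINE == 0.05


def test_mwu_worked_example():
    r = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert r.U == 0.0
    assert r.p_value == pytest.approx(2 / 20)
    assert r.method == "exact"
    r2 = mann_whitney_u([5.0], [5.0])
    assert r2.U == 0.5
    assert r2.p_value == 1.0


def test_mwu_swap_symmetry():
    rng = np.random.default_rng(3)
    for _ in range(30):
        x = rng.integers(0, 6, size=int(rng.integers(2, 7))).astype(float)
        y = rng.integers(0, 6, size=int(rng.integers(2, 7))).astype(float)
        rx = mann_whitney_u(x, y)
        ry = mann_whitney_u(y, x)
        assert rx.U + ry.U == pytest.approx(len(x) * len(y))
        assert rx.p_value == pytest.approx(ry.p_value)


def test_mwu_exact_matches_bruteforce():
    rng = np.random.default_rng(11)
    for _ in range(100):
        n = int(rng.integers(1, 8))
        m = int(rng.integers(1, 8))
        # small integer support to provoke ties often
        x = rng.integers(0, 5, size=n).astype(float)
        y = rng.integers(0, 5, size=m).astype(float)
        got = mann_whitney_u(x, y)
        u, p = mwu_exact_bruteforce(x, y)
        assert got.method == "exact"
        assert got.U == pytest.approx(u)
        assert got.p_value == pytest.approx(p)


def test_mwu_cross_check_scipy_tie_free():
    """Independent check: scipy's exact MWU on tie-free data."""
    rng = np.random.default_rng(17)
    for _ in range(40):
        n = int(rng.integers(2, 8))
        m = int(rng.integers(2, 8))
        pooled = rng.permutation(np.arange(n + m, dtype=float) + rng.random())
        x, y = pooled[:n], pooled[n:]
        ours = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.U == pytest.approx(float(ref.statistic))
        assert ours.p_value == pytest.approx(float(ref.pvalue))


def test_mwu_normal_approximation_large():
    rng = np.random.default_rng(23)
    x = rng.normal(0, 1, size=30)
    y = rng.normal(0.8, 1, size=25)
    ours = mann_whitney_u(x, y)
    assert ours.method == "normal"
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert ours.U == pytest.approx(float(ref.statistic))
    assert ours.p_value == pytest.approx(float(ref.pvalue), rel=1e-6)


def test_bonferroni():
    assert bonferroni_adjust([0.01, 0.4, 1.0]) == [0.03, 1.0, 1.0]
    assert bonferroni_adjust([]) == []
    with pytest.raises(ValueError):
        bonferroni_adjust([0.0])
    with pytest.raises(ValueError):
        bonferroni_adjust([1.5])


def test_compare_groups_structure(table, tiny_db):
    norm = normalize_hit_table(table)
    results = compare_groups(norm, tiny_db)
    assert [r.category for r in results] == [
        "uptake", "evolving", "bidirectional", "bifurcating", "sensory",
    ]
    testable = [r for r in results if r.testable]
    assert len(testable) == 5
    for r in testable:
        assert r.p_bonferroni == pytest.approx(min(1.0, 5 * r.p_raw))
        assert r.n_entries == 1
    frame = comparison_frame(results)
    assert list(frame["category"]) == [r.category for r in results]


def test_compare_groups_untestable_category_excluded_from_correction(tiny_db):
    # drop sensory from the column universe entirely
    counts = {"s1": {"uptake_01": 3}, "s2": {"uptake_01": 1}}
    groups = {"s1": "a", "s2": "b"}
    keep = [e for e in tiny_db.active_ids if e != "sensory_01"]
    table = build_hit_table(counts, groups, entry_ids=keep)
    norm = normalize_hit_table(table)
    results = compare_groups(norm, tiny_db)
    sens = next(r for r in results if r.category == "sensory")
    assert not sens.testable and np.isnan(sens.p_raw)
    for r in results:
        if r.testable:
            assert r.p_bonferroni == pytest.approx(min(1.0, 4 * r.p_raw))
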