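import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from petzones.response import PARAMETERS
from petzones.screening import (
    GroupSummary,
    compare_groups,
    cross_zone,
    group_summary,
    screen_zone,
    select_test,
)

from _oracle import mann_whitney_exact_permutation


class TestSelectTest:
    def test_force_nonparametric_override(self):
        assert select_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6], force_nonparametric=True) == "mann_whitney"

    def test_normal_looking_groups_get_t(self):
        a, b = [1, 2, 3, 4, 5], [2, 3, 4, 5, 6]
        # oracle: both Shapiro-Wilk p-values clear 0.05
        assert stats.shapiro(a).pvalue > 0.05 and stats.shapiro(b).pvalue > 0.05
        assert select_test(a, b) == "t"

    def test_skewed_group_gets_mann_whitney(self):
        a = [1, 1, 1, 1, 1, 1, 1, 100]
        b = [2, 3, 4, 5, 6, 7, 8, 9]
        assert stats.shapiro(a).pvalue < 0.05  # oracle confirms rejection
        assert select_test(a, b) == "mann_whitney"

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            select_test([1, 2], [1, 2, 3])


class TestCompareGroups:
    def test_exact_mann_whitney_on_separated_triples(self):
        # U = 0; 2 of the 20 orderings are as extreme -> p = 0.1
        assert compare_groups([1, 2, 3], [4, 5, 6], "mann_whitney") == pytest.approx(0.1)

    def test_identical_groups_p_is_one(self):
        assert compare_groups([1, 2, 3], [1, 2, 3], "mann_whitney") == pytest.approx(1.0, abs=0.01)

    def test_tied_binary_groups_significant(self):
        p = compare_groups([0, 0, 0, 0], [1, 1, 1, 1], "mann_whitney")
        assert p < 0.05

    def test_exact_p_matches_full_permutation_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            na, nb = rng.integers(3, 6, 2)
            a = rng.uniform(0, 1, na).round(4)
            b = rng.uniform(0, 1, nb).round(4)
            ours = compare_groups(a, b, "mann_whitney")
            ref = mann_whitney_exact_permutation(a, b)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_t_falls_back_to_mann_whitney(self):
        with pytest.warns(UserWarning):
            p = compare_groups([1, 1, 1], [2, 2, 2], "t")
        assert p < 0.2

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        data=st.lists(st.integers(1, 10_000), min_size=8, max_size=14, unique=True)
    )
    def test_mann_whitney_invariant_under_monotone_transform(self, data):
        arr = np.array(data, dtype=float)
        a, b = arr[: len(arr) // 2], arr[len(arr) // 2:]
        p1 = compare_groups(a, b, "mann_whitney")
        p2 = compare_groups(np.log(a), np.log(b), "mann_whitney")
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_label_swap_keeps_p(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 9)
        for test in ("t", "mann_whitney"):
            assert compare_groups(a, b, test) == pytest.approx(compare_groups(b, a, test))


def _labels(n, flags_by_param):
    return {p: np.asarray(flags_by_param[p], bool) for p in PARAMETERS}


class TestScreenZone:
    def _table(self, rng, n, planted=None):
        data = {f"f{i}": rng.normal(0, 1, n) for i in range(30)}
        if planted:
            for name, shift, flags in planted:
                data[name] = rng.normal(0, 1, n) + shift * np.asarray(flags)
        return pd.DataFrame(data)

    def test_three_of_four_rule(self):
        rng = np.random.default_rng(1)
        n = 35
        flags = np.zeros(n, bool)
        flags[:26] = True
        labels = {p: flags for p in PARAMETERS}
        table = self._table(rng, n, planted=[("hit", 3.0, flags)])
        records, results = screen_zone(table, labels, zone=1)
        by = {r.feature: r for r in results}
        assert by["hit"].selected
        assert by["hit"].n_significant_params >= 3
        assert len(records) == len(table.columns) * 4

    def test_two_of_four_not_selected(self):
        from petzones.screening import SelectionResult

        r = SelectionResult("x", 1, 2)
        assert not r.selected
        assert SelectionResult("x", 1, 3).selected

    def test_planted_columns_recovered_null_columns_controlled(self):
        rng = np.random.default_rng(7)
        n = 35
        flags = np.zeros(n, bool)
        flags[:26] = True
        # four labelings: identical groups except independent label noise
        labels = {}
        for p in PARAMETERS:
            f = flags.copy()
            swap = rng.choice(n, 2, replace=False)
            f[swap] = ~f[swap]
            labels[p] = f
        planted = [(f"hit{i}", 2.5, flags) for i in range(5)]
        table = self._table(rng, n, planted=planted)
        _, results = screen_zone(table, labels, zone=1)
        by = {r.feature: r for r in results}
        assert all(by[f"hit{i}"].selected for i in range(5))
        false_rate = np.mean([by[f"f{i}"].selected for i in range(30)])
        assert false_rate < 0.10

    def test_degenerate_parameter_warns_and_counts_nothing(self):
        rng = np.random.default_rng(2)
        n = 12
        flags = np.zeros(n, bool)
        flags[:6] = True
        labels = {p: flags for p in PARAMETERS}
        labels["TL"] = np.ones(n, bool)
        table = self._table(rng, n)
        with pytest.warns(UserWarning):
            records, results = screen_zone(table, labels, zone=2)
        tl_records = [r for r in records if r.parameter == "TL"]
        assert all(not r.significant for r in tl_records)
        assert all(r.n_significant_params <= 3 for r in results)


class TestCrossZone:
    def _records(self, feature, zone, n_sig):
        from petzones.screening import ScreeningRecord

        recs = []
        for i, p in enumerate(PARAMETERS):
            recs.append(ScreeningRecord(feature, zone, p, "t", 0.01 if i < n_sig else 0.5))
        return recs

    def test_feature_significant_everywhere_is_flagged(self):
        from petzones.screening import SelectionResult

        records = {z: self._records("svr", z, 2) for z in (1, 2, 3)}
        results = {z: [SelectionResult("svr", z, 2)] for z in (1, 2, 3)}
        out = cross_zone(records, results, k=1)
        assert all(out[z][0].consistent_across_zones for z in (1, 2, 3))
        out2 = cross_zone(records, results, k=2)
        assert all(out2[z][0].consistent_across_zones for z in (1, 2, 3))

    def test_feature_missing_one_zone_not_flagged(self):
        from petzones.screening import SelectionResult

        records = {z: self._records("x", z, 2 if z < 3 else 0) for z in (1, 2, 3)}
        results = {z: [SelectionResult("x", z, 2)] for z in (1, 2, 3)}
        out = cross_zone(records, results, k=1)
        assert not out[1][0].consistent_across_zones


class TestGroupSummary:
    def test_direction_responders_lower(self):
        gs = group_summary("f", 1, [1, 2, 3, 4, 5, 6], [True, True, True, False, False, False])
        assert gs.direction == "responders_lower"

    def test_median_and_iqr_convention(self):
        gs = group_summary("f", 1, [1, 2, 3, 4, 5, 9, 9, 9], [True] * 5 + [False] * 3)
        assert gs.median_responders == 3.0
        assert gs.iqr_responders == pytest.approx(2.0)

    def test_equal_medians_tie(self):
        gs = group_summary("f", 1, [1, 2, 3, 1, 2, 3], [True] * 3 + [False] * 3)
        assert gs.direction == "tie"

    def test_label_swap_flips_direction(self):
        v = [1, 2, 3, 7, 8, 9]
        flags = np.array([True] * 3 + [False] * 3)
        assert group_summary("f", 1, v, flags).direction == "responders_lower"
        assert group_summary("f", 1, v, ~flags).direction == "responders_higher"
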