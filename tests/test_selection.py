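import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radsurv.errors import DegenerateInputError
from radsurv.selection import (
    bh_adjust,
    build_feature_set_triple,
    correlation_groups,
    optimal_cutpoint,
    percent_change,
    representative_per_group,
    run_selection,
    select_top_k,
    univariate_cox,
)
from radsurv.survival import logrank_scan
from tests.oracles import bh_brute, correlation_components_brute


class TestPercentChange:
    def test_decrease_has_negative_sign(self):
        # worked values: grey-level nonuniformity falling 23.06 -> 16.93
        assert abs(percent_change(23.06, 16.93) - (-26.57)) < 0.1

    def test_increase_has_positive_sign(self):
        assert abs(percent_change(24.13, 43.11) - 78.63) < 0.1

    def test_no_change_is_zero(self):
        assert percent_change(5.7, 5.7) == 0.0

    def test_zero_baseline_flagged_missing(self):
        assert np.isnan(percent_change(0.0, 3.0))

    def test_triple_contains_percent_change(self, rng):
        base = pd.DataFrame(rng.normal(10, 1, (5, 2)), columns=["a", "b"])
        fu = base * 1.1
        triple = build_feature_set_triple(base, fu)
        assert set(triple) == {"baseline", "followup", "percent_change"}
        np.testing.assert_allclose(triple["percent_change"].to_numpy(), 10.0)


class TestCorrelationGroups:
    def test_near_duplicates_grouped(self, rng):
        a = rng.normal(size=50)
        table = pd.DataFrame({"A": a, "B": a + rng.normal(0, 1e-4, 50),
                              "C": rng.normal(size=50)})
        groups = correlation_groups(table)
        assert ["A", "B"] in groups
        assert ["C"] in groups

    def test_anticorrelated_not_grouped_under_signed_rule(self, rng):
        a = rng.normal(size=50)
        table = pd.DataFrame({"A": a, "B": -a})
        assert correlation_groups(table) == [["A"], ["B"]]
        assert correlation_groups(table, use_abs=True) == [["A", "B"]]

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(10):
            base = rng.normal(size=(40, 4))
            mix = rng.normal(size=(4, 10))
            table = pd.DataFrame(base @ mix + 0.05 * rng.normal(size=(40, 10)),
                                 columns=[f"f{i}" for i in range(10)])
            ours = {frozenset(g) for g in correlation_groups(table, 0.95)}
            brute = {frozenset(g) for g in correlation_components_brute(table, 0.95)}
            assert ours == brute

    def test_constant_feature_excluded_with_warning(self, rng):
        table = pd.DataFrame({"A": rng.normal(size=20), "B": np.full(20, 2.0)})
        with pytest.warns(UserWarning, match="constant"):
            groups = correlation_groups(table)
        assert groups == [["A"]]


class TestOptimalCutpoint:
    def test_perfect_separation_found_by_scan(self, rng):
        # two value clusters; survival is unrelated to the feature inside a
        # cluster, so only the between-cluster cutoff separates early from
        # late progressors cleanly
        values = np.concatenate([np.linspace(1.0, 1.45, 10), np.linspace(5.0, 5.45, 10)])
        times = np.concatenate(
            [rng.permutation(np.linspace(2, 5, 10)),
             rng.permutation(np.linspace(18, 25, 10))]
        )
        events = np.ones(20, bool)
        cp = optimal_cutpoint(values, times, events, min_group_frac=0.2)
        assert 1.45 < cp.cutoff < 5.0
        # exhaustive oracle: no admissible cutoff does better
        uniq = np.unique(values)
        cands = np.array([(a + b) / 2 for a, b in zip(uniq[:-1], uniq[1:])
                          if 4 <= (values <= (a + b) / 2).sum() <= 16])
        stats = logrank_scan(times, events, values[:, None] > cands[None, :])
        assert np.isclose(cp.statistic, stats.max())

    def test_matches_exhaustive_scan_on_random_data(self, rng):
        n = 60
        values = rng.normal(size=n)
        times = rng.exponential(10, n)
        events = rng.random(n) < 0.7
        cp = optimal_cutpoint(values, times, events)
        best = -1.0
        uniq = np.unique(values)
        for c in (uniq[:-1] + uniq[1:]) / 2:
            n_below = (values <= c).sum()
            if n_below < 6 or n - n_below < 6:
                continue
            stat = logrank_scan(times, events, (values > c)[:, None])[0]
            best = max(best, stat)
        assert np.isclose(cp.statistic, best)

    def test_constant_feature_rejected(self):
        with pytest.raises(DegenerateInputError):
            optimal_cutpoint(np.ones(20), np.arange(1.0, 21.0), np.ones(20, bool))

    def test_cutoff_strictly_inside_range(self, rng):
        values = rng.normal(size=40)
        cp = optimal_cutpoint(values, rng.exponential(5, 40), np.ones(40, bool))
        assert values.min() < cp.cutoff < values.max()

    def test_minimum_p_inflation_documented(self, rng):
        # a feature unrelated to survival still yields p < 0.05 far more
        # often than 5% when the cutoff is optimized
        hits = 0
        n_sim = 300
        n = 60
        for s in range(n_sim):
            r = np.random.default_rng(s)
            values = r.normal(size=n)
            times = r.exponential(10, n)
            events = r.random(n) < 0.8
            cp = optimal_cutpoint(values, times, events)
            hits += cp.p_logrank < 0.05
        assert hits / n_sim > 0.15  # far above the nominal 5%


class TestUnivariateCox:
    def test_identical_groups_hr_near_one(self):
        times = np.tile(np.arange(1.0, 11.0), 2)
        events = np.ones(20, bool)
        group = np.repeat([0.0, 1.0], 10)
        res = univariate_cox(group, times, events)
        assert abs(res["hr"] - 1.0) < 1e-6

    def test_recovers_true_hazard_ratio(self, rng):
        n = 2000
        group = rng.random(n) < 0.5
        rates = np.where(group, 0.2, 0.1)
        times = rng.exponential(1 / rates)
        res = univariate_cox(group.astype(float), times, np.ones(n, bool))
        assert 1.8 < res["hr"] < 2.2


class TestBHAndTopK:
    def test_hand_worked_step_up(self):
        adjusted = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.3])), [0.3])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_step_up_definition(self, ps):
        p = np.array(ps)
        np.testing.assert_allclose(bh_adjust(p), bh_brute(p), atol=1e-12)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_representative_takes_smallest_p(self):
        groups = [["A", "B"], ["C"]]
        p = {"A": 0.01, "B": 0.02, "C": 0.5}
        assert representative_per_group(groups, p) == ["A", "C"]

    def test_top_k_selects_global_argmin_for_k1(self):
        adjusted = {"a": 0.5, "b": 0.01, "c": 0.3}
        assert select_top_k(adjusted, adjusted, k=1) == ["b"]

    def test_top_k_tie_break_raw_then_name(self):
        adjusted = {"a": 0.2, "b": 0.2, "c": 0.2}
        raw = {"a": 0.15, "b": 0.10, "c": 0.15}
        assert select_top_k(adjusted, raw, k=2) == ["b", "a"]


class TestRunSelection:
    def test_cascade_is_pure_function(self, rng):
        from radsurv.synthetic import CohortSpec, make_cohort

        cohort = make_cohort(CohortSpec(n=60, seed=5))
        triple = {s: cohort.features(s) for s in cohort.feature_sets}
        times, events = cohort.survival()
        r1 = run_selection(triple, times, events)
        r2 = run_selection(triple, times, events)
        assert r1.top_features == r2.top_features
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_clone_block_collapsed_to_one_representative(self):
        from radsurv.synthetic import CohortSpec, make_cohort

        cohort = make_cohort(CohortSpec(n=80, seed=9, clone_block=True))
        triple = {s: cohort.features(s) for s in cohort.feature_sets}
        times, events = cohort.survival()
        report = run_selection(triple, times, events)
        for set_name, groups in report.groups.items():
            clone_groups = [g for g in groups if "clone_a" in g]
            assert clone_groups and "clone_b" in clone_groups[0]
        per_set = report.table[report.table.representative]
        for set_name in triple:
            reps = per_set[per_set.set == set_name].feature.tolist()
            assert not ({"clone_a", "clone_b"} <= set(reps))
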