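import numpy as np
import pandas as pd
import pytest

from radsurv.errors import DegenerateInputError, ValidationError
from radsurv.survival import (
    SurvivalData,
    backward_stepwise,
    bootstrap_compare,
    cox_fit,
    harrell_c,
    km_curve,
    logrank_test,
    median_lp_risk_groups,
)
from tests.oracles import efron_partial_loglik, harrell_c_brute


def two_group_data(rng, n=200, hr=2.0, censor=0.0):
    group = rng.random(n) < 0.5
    rates = 0.1 * np.where(group, hr, 1.0)
    t_event = rng.exponential(1 / rates)
    if censor > 0:
        t_cens = rng.exponential(1 / (0.1 * censor), size=n)
        times = np.minimum(t_event, t_cens)
        events = t_event <= t_cens
    else:
        times, events = t_event, np.ones(n, bool)
    return SurvivalData(times, events, pd.DataFrame({"group": group.astype(float)}))


class TestCoxFit:
    def test_constant_zero_covariate_gives_null_effect(self):
        data = SurvivalData(
            np.arange(1.0, 11.0), np.ones(10, bool), pd.DataFrame({"x": np.zeros(10)})
        )
        with pytest.warns(UserWarning, match="constant"):
            fit = cox_fit(data)
        assert fit.coefficients["x"] == 0.0
        assert fit.hazard_ratios["x"] == 1.0

    def test_recovers_log_hazard_ratio(self, rng):
        data = two_group_data(rng, n=5000, hr=2.0)
        fit = cox_fit(data)
        assert abs(fit.coefficients["group"] - np.log(2)) < 0.05

    def test_six_patient_fit_matches_grid_search_oracle(self):
        times = np.array([2.0, 3.0, 3.0, 5.0, 8.0, 9.0])
        events = np.array([1, 1, 1, 1, 0, 1], bool)
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        fit = cox_fit(SurvivalData(times, events, pd.DataFrame({"x": x})))
        grid = np.linspace(-5, 5, 2001)
        ll = [efron_partial_loglik(b, times, events, x) for b in grid]
        coarse = grid[int(np.argmax(ll))]
        fine = np.linspace(coarse - 0.01, coarse + 0.01, 4001)
        ll_fine = [efron_partial_loglik(b, times, events, x) for b in fine]
        best = fine[int(np.argmax(ll_fine))]
        assert abs(fit.coefficients["x"] - best) < 1e-4

    def test_collinear_covariates_named_in_error(self, rng):
        x = rng.normal(size=50)
        data = SurvivalData(
            rng.exponential(10, 50), np.ones(50, bool),
            pd.DataFrame({"a": x, "b": 2 * x}),
        )
        with pytest.raises(ValidationError, match="'a' and 'b'"):
            cox_fit(data)

    def test_ci_brackets_hazard_ratio(self, rng):
        fit = cox_fit(two_group_data(rng, n=300))
        assert fit.ci_lower["group"] <= fit.hazard_ratios["group"] <= fit.ci_upper["group"]

    def test_too_few_events_rejected(self, rng):
        data = SurvivalData(
            np.arange(1.0, 4.0), np.array([True, False, False]),
            pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 1.0, 4.0]}),
        )
        with pytest.raises(DegenerateInputError):
            cox_fit(data)


class TestBackwardStepwise:
    def test_single_strong_covariate_retained(self, rng):
        data = two_group_data(rng, n=400, hr=3.0)
        fit = backward_stepwise(data)
        assert fit.covariate_names == ["group"]
        assert fit.dropped == ()

    def test_noise_covariates_dropped(self, rng):
        base = two_group_data(rng, n=400, hr=3.0)
        cov = base.covariates.copy()
        cov["noise1"] = rng.normal(size=400)
        cov["noise2"] = rng.normal(size=400)
        fit = backward_stepwise(SurvivalData(base.time, base.event, cov))
        assert "group" in fit.covariate_names
        assert set(fit.dropped) <= {"noise1", "noise2"}

    def test_all_null_covariates_gives_empty_model(self, rng):
        n = 100
        data = SurvivalData(
            rng.exponential(10, n), np.ones(n, bool),
            pd.DataFrame({"n1": rng.normal(size=n), "n2": rng.normal(size=n)}),
        )
        fit = backward_stepwise(data)
        if not fit.covariate_names:  # overwhelmingly likely under the null
            assert set(fit.dropped) == {"n1", "n2"}

    def test_retained_model_log_likelihood_dominates_submodels(self, rng):
        data = two_group_data(rng, n=300, hr=2.5)
        cov = data.covariates.copy()
        cov["x2"] = rng.normal(size=300) + 0.5 * cov["group"]
        full = SurvivalData(data.time, data.event, cov)
        fit = backward_stepwise(full, alpha_remove=0.9999)  # keep everything
        for name in fit.covariate_names:
            reduced = cox_fit(full.subset_covariates(
                [c for c in fit.covariate_names if c != name]))
            assert fit.log_likelihood >= reduced.log_likelihood - 1e-8


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = np.tile(np.arange(1.0, 6.0), 2)
        events = np.ones(10, bool)
        group = np.repeat([False, True], 5)
        stat, p = logrank_test(times, events, group)
        assert abs(stat) < 1e-12
        assert p > 0.999

    def test_label_swap_symmetry(self, rng):
        times = rng.exponential(10, 30)
        events = rng.random(30) < 0.8
        group = rng.random(30) < 0.4
        s1, _ = logrank_test(times, events, group)
        s2, _ = logrank_test(times, events, ~group)
        assert np.isclose(s1, s2)

    def test_hand_computed_risk_table(self):
        # 5+5 subjects, all events, manual O-E arithmetic
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        events = np.ones(10, bool)
        group = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], bool)
        # observed deaths in group 1 = 5; expected = sum over deaths of n1/n
        expected = sum(
            [(5 - min(k, 5)) / (10 - k) if k < 5 else 0 for k in range(10)]
        )
        o_minus_e = 5 - sum((5 - k) / (10 - k) for k in range(5))
        stat, p = logrank_test(times, events, group)
        from lifelines.statistics import logrank_test as ll

        ref = ll(times[group], times[~group], events[group], events[~group])
        assert np.isclose(stat, ref.test_statistic)
        assert o_minus_e > 0  # sanity of the manual arithmetic

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines.statistics import logrank_test as ll

        times = rng.exponential(10, 60)
        events = rng.random(60) < 0.7
        group = rng.random(60) < 0.5
        stat, p = logrank_test(times, events, group)
        ref = ll(times[group], times[~group], events[group], events[~group])
        assert np.isclose(stat, ref.test_statistic)
        assert np.isclose(p, ref.p_value)

    def test_one_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test(np.arange(1.0, 6.0), np.ones(5, bool), np.zeros(5, bool))


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        table = km_curve(np.arange(1.0, 6.0), np.zeros(5, bool))
        assert (table["survival"] >= 1.0 - 1e-12).all()

    def test_four_distinct_events_quarter_steps(self):
        table = km_curve(np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4, bool))
        steps = table[table["time"] > 0]["survival"].to_numpy()
        np.testing.assert_allclose(steps, [0.75, 0.5, 0.25, 0.0])

    def test_median_of_synthetic_cohort_near_target(self):
        from radsurv.synthetic import CohortSpec, make_cohort

        cohort = make_cohort(CohortSpec(n=2000, seed=42))
        times, events = cohort.survival()
        table = km_curve(times, events)
        assert abs(table.attrs["median"] - 9.7) < 1.5


class TestHarrellC:
    def test_perfect_predictor(self):
        times = np.arange(1.0, 11.0)
        assert harrell_c(-times, times, np.ones(10, bool)) == 1.0

    def test_random_predictor_near_half(self, rng):
        n = 3000
        c = harrell_c(rng.normal(size=n), rng.exponential(10, n), np.ones(n, bool))
        assert abs(c - 0.5) < 0.03

    def test_matches_brute_force_exactly(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 120))
            times = rng.exponential(10, n).round(0) + 1  # force some ties
            events = rng.random(n) < 0.7
            lp = rng.normal(size=n).round(1)
            if not events.any() or not (times[events][:, None] < times[None, :]).any():
                continue
            assert harrell_c(lp, times, events) == harrell_c_brute(lp, times, events)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(DegenerateInputError):
            harrell_c(np.array([1.0, 2.0]), np.array([5.0, 5.0]), np.array([True, True]))


class TestBootstrapCompare:
    def _models(self, rng, n=150):
        lp_true = rng.normal(size=n)
        times = rng.exponential(np.exp(-lp_true) * 10)
        events = rng.random(n) < 0.8
        models = {
            "good": lp_true + rng.normal(0, 0.5, n),
            "bad": rng.normal(size=n),
        }
        return models, times, events

    def test_better_model_detected(self, rng):
        models, times, events = self._models(rng, n=300)
        res = bootstrap_compare(models, times, events, B=300, seed=1)
        assert res.c_original["good"] > res.c_original["bad"]
        assert res.pairwise_p[("good", "bad")] < 0.01

    def test_seed_determinism(self, rng):
        models, times, events = self._models(rng)
        r1 = bootstrap_compare(models, times, events, B=100, seed=7)
        r2 = bootstrap_compare(models, times, events, B=100, seed=7)
        assert r1.c_mean == r2.c_mean
        pd.testing.assert_frame_equal(r1.replicates, r2.replicates)

    def test_model_against_itself_flagged(self, rng):
        models, times, events = self._models(rng)
        dup = {"m1": models["good"], "m2": models["good"].copy()}
        res = bootstrap_compare(dup, times, events, B=50, seed=3)
        assert np.isnan(res.pairwise_p[("m1", "m2")])


class TestRiskGroups:
    def test_near_constant_lp_splits_half_half(self, rng):
        n = 41
        lp = 1.0 + 1e-9 * rng.normal(size=n)
        times = rng.exponential(10, n)
        events = np.ones(n, bool)
        res = median_lp_risk_groups(lp, times, events)
        assert res.group_high.sum() in (n // 2, n // 2 + 1)

    def test_constant_lp_rejected(self):
        with pytest.raises(DegenerateInputError):
            median_lp_risk_groups(np.ones(10), np.arange(1.0, 11.0), np.ones(10, bool))

    def test_prognostic_lp_gives_hr_above_one(self, rng):
        n = 200
        lp = rng.normal(size=n)
        times = rng.exponential(np.exp(-lp) * 10)
        res = median_lp_risk_groups(lp, times, np.ones(n, bool))
        assert res.hr > 1.5
        assert res.logrank_p < 0.01
        assert res.ci[0] <= res.hr <= res.ci[1]
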