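"""Survival projection, Kaplan-Meier construction, and the log-rank test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import metkit as mk


POWER_CFG = mk.ProjectionConfig(family="power", exponent=4.1, threshold_mm2=300.0)
EXP_CFG = mk.ProjectionConfig(family="exponential", exponent=0.45, threshold_mm2=300.0)


class TestProjectMouse:
    @pytest.mark.parametrize("config", [POWER_CFG, EXP_CFG])
    def test_mouse_at_threshold_crosses_at_measurement_day(self, config):
        r = mk.project_mouse(300.0, 14.0, config)
        assert r.crossing_day == pytest.approx(14.0, rel=1e-12)
        assert r.flag == "above_threshold"

    def test_exponential_closed_form(self):
        r = mk.project_mouse(50.0, 14.0, EXP_CFG)
        assert r.amplitude_i == pytest.approx(50.0 * np.exp(-0.45 * 14.0), rel=1e-12)
        assert r.amplitude_i == pytest.approx(0.0918, abs=2e-4)
        assert r.crossing_day == pytest.approx(np.log(300.0 / r.amplitude_i) / 0.45, rel=1e-12)
        assert r.crossing_day == pytest.approx(18.0, abs=0.05)

    def test_power_closed_form(self):
        r = mk.project_mouse(95.2, 14.0, POWER_CFG)
        assert r.amplitude_i == pytest.approx(95.2 / 14.0**4.1, rel=1e-12)
        assert r.amplitude_i == pytest.approx(0.0019, abs=5e-5)
        assert r.crossing_day == pytest.approx(18.5, abs=0.05)

    @settings(deadline=None, derandomize=True, max_examples=80)
    @given(
        area=st.floats(1e-3, 400.0),
        day=st.floats(5.0, 25.0),
        exponent=st.floats(0.2, 6.0),
        family=st.sampled_from(["power", "exponential"]),
    )
    def test_round_trip_consistency(self, area, day, exponent, family):
        # forward-evaluating the individual curve at the crossing day must
        # return the threshold
        config = mk.ProjectionConfig(family=family, exponent=exponent)
        r = mk.project_mouse(area, day, config)
        fit = mk.GrowthFit(family=family, amplitude=r.amplitude_i, exponent=exponent)
        assert mk.predict_area(fit, r.crossing_day) == pytest.approx(
            config.threshold_mm2, rel=1e-9)

    def test_larger_area_crosses_earlier(self):
        days = [mk.project_mouse(a, 14.0, POWER_CFG).crossing_day
                for a in (10.0, 50.0, 100.0, 250.0)]
        assert np.all(np.diff(days) < 0)

    def test_zero_area_censored(self):
        r = mk.project_mouse(0.0, 14.0, POWER_CFG)
        assert r.flag == "zero_area" and not r.event
        assert r.event_time == 14.0 and np.isnan(r.crossing_day)

    def test_above_threshold_enters_km_at_measurement_day(self):
        r = mk.project_mouse(450.0, 14.0, POWER_CFG)
        assert r.flag == "above_threshold"
        assert r.crossing_day < 14.0
        assert r.event_time == 14.0 and r.event


class TestProjectCohort:
    def test_identical_mice_identical_crossings(self):
        recs = [mk.BurdenRecord(f"m{i}", "g", 14.0, 95.2) for i in range(6)]
        proj = mk.project_cohort(recs, POWER_CFG)
        days = {r.crossing_day for r in proj.results}
        assert len(days) == 1
        assert proj.median_crossing_day == pytest.approx(days.pop())

    def test_cohort_on_printed_exponential_curve(self, exponential_fit):
        # mice lying exactly on the calibrated exponential all cross at
        # the cohort closed-form crossing time (~19-20 days)
        expected = mk.crossing_time(exponential_fit, 300.0)
        recs = [
            mk.BurdenRecord(f"m{i}", "wt", d, mk.predict_area(exponential_fit, d))
            for i, d in enumerate([10.0, 12.0, 14.0, 16.0])
        ]
        proj = mk.project_cohort(recs, EXP_CFG)
        for r in proj.results:
            assert r.crossing_day == pytest.approx(expected, rel=1e-12)
        assert 19.0 <= proj.median_crossing_day <= 20.0

    def test_treated_outlives_untreated_in_projection(self):
        # cohorts simulated at the calibrated power laws: projected median
        # survival ordered treated > untreated in >= 95% of replicates
        wins = 0
        n_rep = 100
        for seed in range(n_rep):
            medians = {}
            for make_spec, group in [(mk.untreated_power_spec, "untreated"),
                                     (mk.treated_power_spec, "treated")]:
                recs, _ = mk.gen_cohort(make_spec(seed=seed))
                fit = mk.fit_growth(recs, family="power")
                proj = mk.project_cohort(recs, mk.ProjectionConfig.from_fit(fit))
                medians[group] = proj.median_crossing_day
            wins += medians["treated"] > medians["untreated"]
        assert wins >= 0.95 * n_rep


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        km = mk.build_km([18, 19, 20, 21, 22], [True] * 5)
        assert km.survival_prob == pytest.approx((0.8, 0.6, 0.4, 0.2, 0.0))
        assert km.n_at_risk == (5, 4, 3, 2, 1)
        assert km.median() == 20

    def test_all_censored_stays_at_one(self):
        km = mk.build_km([5, 8, 13], [False, False, False])
        assert all(s == 1.0 for s in km.survival_prob)
        assert np.isnan(km.median())

    def test_single_event_among_n(self):
        km = mk.build_km([7, 8, 9, 11], [True, False, False, False])
        assert km.survival_at(7) == pytest.approx(3 / 4)
        assert km.survival_at(6.9) == 1.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.integers(1, 30, size=40).astype(float)
        km = mk.build_km(times, [True] * 40)
        for t in np.unique(times):
            assert km.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_survival_non_increasing_and_starts_below_one(self, rng):
        times = rng.exponential(10, size=30) + 1
        events = rng.random(30) < 0.7
        km = mk.build_km(times, events)
        s = np.array(km.survival_prob)
        assert np.all(np.diff(s) <= 1e-12)
        assert s[0] <= 1.0

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        kmf = lifelines.KaplanMeierFitter()
        for _ in range(10):
            times = rng.integers(1, 15, size=20).astype(float)
            events = rng.random(20) < 0.7
            if not events.any():
                continue
            kmf.fit(times, events)
            km = mk.build_km(times, events)
            for t in np.unique(times):
                ref = float(kmf.survival_function_at_times(t).iloc[0])
                assert km.survival_at(t) == pytest.approx(ref, abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mk.build_km([], [])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = ([3, 5, 7], [True, True, True])
        chi2, p = mk.logrank(g, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # A events {1,2}, B events {3,4}: O_A=2, E_A=5/6, V=17/36
        chi2, p = mk.logrank(([1, 2], [True, True]), ([3, 4], [True, True]))
        assert chi2 == pytest.approx((2 - 5 / 6) ** 2 / (17 / 36), rel=1e-12)
        assert chi2 == pytest.approx(2.88, abs=0.01)

    def test_label_swap_symmetry(self, rng):
        a = (rng.integers(1, 20, 12).astype(float), rng.random(12) < 0.8)
        b = (rng.integers(1, 20, 9).astype(float), rng.random(9) < 0.8)
        assert mk.logrank(a, b)[0] == pytest.approx(mk.logrank(b, a)[0], rel=1e-12)

    def test_no_events_anywhere(self):
        chi2, p = mk.logrank(([2, 3], [False, False]), ([4], [False]))
        assert (chi2, p) == (0.0, 1.0)

    def test_matches_lifelines_on_random_data(self, rng):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        for _ in range(100):
            na, nb = rng.integers(3, 12, size=2)
            ta = rng.integers(1, 25, na).astype(float)
            tb = rng.integers(1, 25, nb).astype(float)
            ea = rng.random(na) < 0.8
            eb = rng.random(nb) < 0.8
            chi2, p = mk.logrank((ta, ea), (tb, eb))
            ref = lifelines_stats.logrank_test(ta, tb, event_observed_A=ea,
                                               event_observed_B=eb)
            assert chi2 == pytest.approx(ref.test_statistic, abs=1e-6)
            assert p == pytest.approx(ref.p_value, abs=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mk.logrank(([], []), ([1], [True]))
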