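"""Simulation engine: shared pre-therapy phase, milestones, dose
accounting, event-located switching and solver robustness."""

import numpy as np
import pytest

import evotherapy as et
from evotherapy.simulation_engine import milestone_times, progression_time


def pre_trigger(result):
    s = result.series
    return s[s["t"] <= result.trigger_time].reset_index(drop=True)


class TestSharedPhase:
    def test_pre_trigger_trajectories_identical_across_regimens(self, p2_results):
        reference = pre_trigger(p2_results["untreated"])
        for name, result in p2_results.items():
            frame = pre_trigger(result)
            assert np.array_equal(frame["t"], reference["t"]), name
            for col in ("x1", "x2", "x3", "psa"):
                assert np.array_equal(frame[col], reference[col]), (name, col)
            assert not frame["drug_on"].any()

    def test_trigger_fires_at_80pct_of_equilibrium_psa(self, patient2,
                                                       p2_results):
        psa_star = et.untreated_ess(patient2).psa_star
        for result in p2_results.values():
            assert result.baseline_psa == pytest.approx(0.8 * psa_star,
                                                        rel=1e-6)
            assert result.trigger_time == p2_results["mtd"].trigger_time

    def test_early_resistant_takeoff_is_regimen_independent(self, p2_results):
        times = {k: r.milestones["tminus_5pct"] for k, r in p2_results.items()}
        assert all(t is not None for t in times.values())
        reference = times["untreated"]
        assert all(t == pytest.approx(reference, rel=1e-9)
                   for t in times.values())


class TestMilestones:
    def test_thresholds_are_reached_in_order(self, p1_results, p2_results):
        for result in list(p1_results.values()) + list(p2_results.values()):
            t5 = result.milestones["tminus_5pct"]
            t90 = result.milestones["tminus_90pct"]
            if t5 is not None and t90 is not None:
                assert t5 <= t90

    def test_threshold_below_initial_frequency_reports_time_zero(self,
                                                                 p2_results):
        # patient 2 starts with T- at 2.4% of cells
        times = milestone_times(p2_results["untreated"], [0.01])
        assert times[0.01] == 0.0

    def test_interpolated_times_match_event_located_times(self, p2_results):
        result = p2_results["mtd"]
        times = milestone_times(result, [0.05, 0.90])
        assert times[0.05] == pytest.approx(result.milestones["tminus_5pct"],
                                            abs=0.05)
        assert times[0.90] == pytest.approx(result.milestones["tminus_90pct"],
                                            abs=0.05)

    def test_milestones_stable_under_tighter_tolerances(self, patient2):
        loose = et.simulate(patient2, et.RegimenSpec.mtd())
        tight = et.simulate(
            patient2, et.RegimenSpec.mtd(),
            solver=et.SolverConfig(rel_tol=1e-9, abs_tol=1e-11),
        )
        for key in ("tminus_5pct", "tminus_90pct"):
            a, b = loose.milestones[key], tight.milestones[key]
            assert abs(a - b) / b < 1e-3


class TestTrajectories:
    def test_abundances_never_negative(self, p1_results, p2_results):
        for result in list(p1_results.values()) + list(p2_results.values()):
            values = result.series[["x1", "x2", "x3", "psa"]].to_numpy()
            assert values.min() >= 0.0

    def test_untreated_run_settles_at_the_ess(self, patient2, p2_results):
        ess = et.untreated_ess(patient2)
        tail = p2_results["untreated"].series.iloc[-1]
        final = np.array([tail.x1, tail.x2, tail.x3])
        assert np.abs(final - ess.abundances).max() / ess.total < 1e-3

    def test_zero_inoculum_keeps_resistant_clone_at_zero(self, patient1):
        result = et.simulate(
            patient1, et.RegimenSpec.mtd(),
            solver=et.SolverConfig(horizon_days=1500.0), inoculum=0.0,
        )
        assert np.all(result.series["x3"].to_numpy() == 0.0)
        assert result.milestones["tminus_5pct"] is None
        assert result.milestones["tminus_90pct"] is None

    def test_series_sampling_is_at_most_daily(self, p2_results):
        t = p2_results["adaptive"].series["t"].to_numpy()
        assert np.diff(t).max() <= 1.0 + 1e-9


class TestAdaptivePolicy:
    def test_switches_happen_at_the_hysteresis_thresholds(self, p2_results):
        result = p2_results["adaptive"]
        lower = result.regimen.adaptive_lower * result.baseline_psa
        upper = result.regimen.adaptive_upper * result.baseline_psa
        s = result.series
        for k, (start, end) in enumerate(result.ledger.on_intervals):
            psa_start = np.interp(start, s["t"], s["psa"])
            psa_end = np.interp(end, s["t"], s["psa"])
            if k > 0:
                assert psa_start == pytest.approx(upper, rel=5e-3)
            if end < s["t"].iloc[-1] - 1.0:
                assert psa_end == pytest.approx(lower, rel=5e-3)

    def test_drug_never_exceeds_the_restart_threshold(self, p2_results):
        # after the first switch the policy caps PSA at its baseline
        result = p2_results["adaptive"]
        first_off = result.ledger.on_intervals[0][1]
        post = result.series[result.series["t"] > first_off]
        assert post["psa"].max() <= result.baseline_psa * 1.01

    def test_interval_monitoring_switches_only_at_visits(self, patient2):
        spec = et.RegimenSpec.adaptive().with_monitoring(et.Monitoring.INTERVAL)
        result = et.simulate(patient2, spec,
                             solver=et.SolverConfig(horizon_days=2000.0))
        for start, end in result.ledger.on_intervals:
            for edge in (start, end):
                if edge >= result.trigger_time and \
                        edge < result.series["t"].iloc[-1] - 1e-6:
                    k = (edge - result.trigger_time) / 28.0
                    assert k == pytest.approx(round(k), abs=1e-6)

    def test_adaptive_delays_competitive_release(self, p1_results, p2_results):
        for results in (p1_results, p2_results):
            mtd, ada = results["mtd"], results["adaptive"]
            assert ada.milestones["tminus_90pct"] > mtd.milestones["tminus_90pct"]
            assert ada.milestones["progression"] > mtd.milestones["progression"]


class TestDoseAccounting:
    def test_mtd_dose_is_exactly_100(self, p1_results, p2_results):
        for results in (p1_results, p2_results):
            res = results["mtd"]
            assert res.dose_pct(end=res.milestones["progression"]) == 100.0

    def test_untreated_dose_is_zero(self, p2_results):
        assert p2_results["untreated"].dose_pct() == 0.0

    def test_adaptive_uses_far_less_drug_than_mtd(self, p1_results,
                                                  p2_results):
        for results in (p1_results, p2_results):
            ada = results["adaptive"]
            assert ada.dose_pct(end=ada.milestones["progression"]) < 25.0

    def test_metronomic_duty_cycle_over_full_horizon(self, p2_results):
        # 240-day induction then 28/112 duty: a bit above 25% over 10000 days
        res = p2_results["metronomic"]
        assert 24.0 < res.dose_pct() < 32.0


class TestProgression:
    def test_untreated_progression_is_undefined(self, p1_results, p2_results):
        assert p1_results["untreated"].milestones["progression"] is None
        assert p2_results["untreated"].milestones["progression"] is None

    def test_mtd_progression_follows_takeover(self, p2_results):
        res = p2_results["mtd"]
        prog = res.milestones["progression"]
        assert prog is not None
        assert prog >= res.milestones["tminus_90pct"]
        assert res.terminated is et.Termination.PROGRESSION

    def test_progression_requires_sustained_psa(self, p2_results):
        # recomputing with an absurdly long window must postpone or void it
        res = p2_results["mtd"]
        longer = progression_time(res, window_days=20_000.0)
        assert longer is None


class TestCompareRegimens:
    def test_table_shape_and_contents(self, patient2):
        specs = [et.RegimenSpec.untreated(), et.RegimenSpec.mtd(),
                 et.RegimenSpec.adaptive()]
        table = et.compare_regimens(
            patient2, specs, solver=et.SolverConfig(horizon_days=400.0))
        assert list(table["regimen"]) == ["untreated", "mtd", "adaptive"]
        assert set(table.columns) >= {"trigger_time", "tminus_5pct",
                                      "tminus_90pct", "progression",
                                      "dose_pct", "terminated"}
        assert table.loc[0, "dose_pct"] == 0.0
        assert table.loc[1, "dose_pct"] == 100.0
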