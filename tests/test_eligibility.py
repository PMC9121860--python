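import numpy as np
import pytest

from cd4time.eligibility import (
    build_followup_windows,
    detect_virologic_failure,
    determine_followup_end,
    find_baseline_cd4,
    find_first_vs,
)
from cd4time.pipeline import RunConfig
from cd4time.synthetic import SimConfig, generate_cohort
from oracles import brute_force_failure_scan, brute_force_followup_end

CLOSURE = 4000


class TestBaselineCD4:
    def test_closest_measurement_wins(self):
        res = find_baseline_cd4(np.array([-10, 20]), np.array([80.0, 120.0]))
        assert res == (80.0, -10)

    def test_outside_window_is_none(self):
        assert find_baseline_cd4(np.array([-120]), np.array([80.0])) is None

    def test_window_bounds_inclusive(self):
        assert find_baseline_cd4(np.array([-90]), np.array([50.0])) == (50.0, -90)
        assert find_baseline_cd4(np.array([30]), np.array([50.0])) == (50.0, 30)
        assert find_baseline_cd4(np.array([-91, 31]), np.array([1.0, 2.0])) is None

    def test_equidistant_tie_prefers_pre_art(self):
        res = find_baseline_cd4(np.array([-15, 15]), np.array([90.0, 210.0]))
        assert res == (90.0, -15)


class TestFirstSuppression:
    def test_single_suppressed_vl(self):
        assert find_first_vs(np.array([95]), np.array([150.0])) == 95

    def test_after_twelve_months_excluded(self):
        assert find_first_vs(np.array([395]), np.array([150.0])) is None

    def test_earliest_qualifying_date(self):
        days = np.array([60, 150, 210])
        vals = np.array([300.0, 150.0, 80.0])
        assert find_first_vs(days, vals) == 150

    def test_threshold_strict(self):
        assert find_first_vs(np.array([100]), np.array([200.0])) is None
        assert find_first_vs(np.array([100]), np.array([199.0])) == 100


class TestVirologicFailure:
    def test_single_high_vl(self):
        assert detect_virologic_failure(np.array([10, 40]), np.array([50.0, 1500.0])) == 40

    def test_two_consecutive_above_200(self):
        days = np.array([10, 20, 30, 40, 50])
        vals = np.array([50.0, 400.0, 90.0, 450.0, 600.0])
        assert detect_virologic_failure(days, vals) == 50

    def test_no_failure_when_rules_never_hold(self):
        days = np.array([10, 20, 30, 40, 50])
        vals = np.array([50.0, 400.0, 90.0, 700.0, 95.0])
        assert detect_virologic_failure(days, vals) is None

    def test_exactly_200_does_not_count_as_high(self):
        assert detect_virologic_failure(np.array([1, 2]), np.array([200.0, 200.0])) is None
        assert detect_virologic_failure(np.array([1, 2]), np.array([201.0, 201.0])) == 2
        assert detect_virologic_failure(np.array([1]), np.array([1000.0])) is None

    def test_agrees_with_brute_force_scan_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = rng.integers(1, 12)
            days = np.sort(rng.choice(2000, size=n, replace=False))
            vals = rng.choice([50.0, 150.0, 300.0, 600.0, 1500.0], size=n)
            assert detect_virologic_failure(days, vals) == brute_force_failure_scan(days, vals)


class TestFollowupEnd:
    def _end(self, cd4_days, vl, t_vs=0, closure=CLOSURE, death=None):
        vl_days = np.array([d for d, _ in vl])
        vl_vals = np.array([v for _, v in vl], dtype=float)
        labs = np.concatenate([np.asarray(cd4_days), vl_days])
        return determine_followup_end(labs, vl_days, vl_vals, t_vs, closure,
                                      death_day=death)

    def test_death_within_year_of_last_suppressed_vl(self):
        end, reason = self._end([0, 300, 600], [(0, 50.0), (900, 100.0)], death=1100)
        assert (end, reason) == (1100, "death")

    def test_final_nonsuppressed_vl_censors_at_last_suppressed(self):
        end, reason = self._end([0, 300, 600], [(0, 50.0), (700, 90.0), (800, 350.0)])
        assert (end, reason) == (700, "final_vl_nonsuppressed")

    def test_year_long_lab_gap_censors_at_last_measurement(self):
        end, reason = self._end([100, 600], [(0, 50.0)], closure=900)
        assert (end, reason) == (100, "gap_censor")

    def test_death_wins_same_day_tie_with_failure(self):
        end, reason = self._end([0], [(0, 50.0), (300, 5000.0)], death=300)
        assert (end, reason) == (300, "death")

    def test_death_beyond_year_after_last_vl_is_not_event(self):
        end, reason = self._end([0], [(0, 50.0)], death=400, closure=CLOSURE)
        assert reason != "death"
        assert end <= 365

    def test_agrees_with_day_by_day_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(4)
        for _ in range(120):
            args = random_followup_fixture(rng)
            got = determine_followup_end(*args[:5], death_day=args[5])
            want = brute_force_followup_end(args[6], args[1], args[2], args[3],
                                            args[4], death_day=args[5])
            assert got == want, f"fixture {args}"


def random_followup_fixture(rng):
    """Random small lab history with a guaranteed suppressed VL at t_vs."""
    t_vs = int(rng.integers(0, 200))
    closure = int(rng.integers(t_vs + 100, t_vs + 2500))
    n_vl = int(rng.integers(0, 10))
    n_cd4 = int(rng.integers(0, 10))
    pool = rng.choice(np.arange(t_vs + 1, t_vs + 2600), size=n_vl + n_cd4, replace=False)
    vl_days = np.concatenate([[t_vs], np.sort(pool[:n_vl])])
    vl_vals = np.concatenate([[float(rng.integers(10, 199))],
                              rng.choice([50.0, 150.0, 250.0, 600.0, 1500.0, 50000.0],
                                         size=n_vl)])
    cd4_days = np.sort(pool[n_vl:])
    death = int(rng.integers(t_vs, t_vs + 2600)) if rng.random() < 0.35 else None
    labs = np.concatenate([cd4_days, vl_days])
    return labs, vl_days, vl_vals, t_vs, closure, death, cd4_days


class TestCohortWindows:
    def test_no_failure_no_ltfu_no_death_ends_admin_at_closure(self):
        cfg = SimConfig(n_patients=80, seed=21, failure_rate=0.0, ltfu_rate=0.0,
                        baseline_hazard={"death": 0.0, "ade": 0.0, "snade": 0.0},
                        p_missing_baseline=0.0,
                        visit_gap_q=(90.0, 120.0, 150.0), visit_gap_max=300.0)
        cohort, _ = generate_cohort(cfg)
        windows, excl = build_followup_windows(cohort, "2019-12-31")
        assert set(windows["end_reason"]) == {"admin_censor"}
        starts = cohort.patients.set_index("patient_id")["art_start_date"]
        import pandas as pd
        for w in windows.itertuples(index=False):
            closure = (pd.Timestamp("2019-12-31") - starts[w.patient_id]).days
            assert w.end_day == closure

    def test_flow_counts_conserved(self, small_cohort):
        cohort, _ = small_cohort
        windows, excl = build_followup_windows(cohort, "2019-12-31")
        assert len(windows) + len(excl) == len(cohort.patients)
        assert set(windows["patient_id"]).isdisjoint(excl["patient_id"])

    def test_window_invariants(self, small_cohort):
        cohort, _ = small_cohort
        windows, _ = build_followup_windows(cohort, "2019-12-31")
        assert (windows["end_day"] >= windows["t_vs"]).all()
        assert (windows["t_vs"] <= 365).all()
        assert windows["baseline_cd4_day"].between(-90, 30).all()
        lt = windows["baseline_cd4"] < 200
        assert (windows.loc[lt, "baseline_group"] == "lt200").all()
        assert (windows.loc[~lt, "baseline_group"] == "ge200").all()
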