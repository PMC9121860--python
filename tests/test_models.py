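import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test

from cd4time.models import (
    NoEventsError,
    compare_aic,
    encode_covariates,
    fit_cox,
    fit_fractional_logit,
    hr_contrast,
    predict_survival,
    recover_per_unit_coefficient,
    schoenfeld_ph_test,
)
from oracles import brute_force_log_partial_likelihood


def exponential_cox_data(n, beta, rate=0.01, seed=0, censor_at=200.0):
    """Constant binary covariate, exponential event times with true log-HR beta."""
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, n).astype(float)
    t = rng.exponential(1.0 / (rate * np.exp(beta * x)))
    stop = np.minimum(t, censor_at)
    return pd.DataFrame({
        "patient_id": np.arange(n).astype(str),
        "start": 0.0, "stop": stop, "event": (t <= censor_at).astype(int),
        "pct_below": x,
    })


def fit_simple(df):
    return fit_cox(df, "pct_only", adjustment=[], strata=None)


class TestFitCox:
    def test_constant_binary_covariate_recovers_hr2(self):
        df = exponential_cox_data(3000, np.log(2.0), seed=1)
        fit = fit_simple(df)
        beta, se = fit.params["pct_below"], fit.se["pct_below"]
        assert beta - 1.96 * se < np.log(2.0) < beta + 1.96 * se

    def test_null_covariate_gives_near_zero_coefficient(self):
        inside = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            df = exponential_cox_data(500, 0.0, seed=200 + seed)
            df["pct_below"] = rng.normal(size=len(df))
            fit = fit_simple(df)
            z = fit.params["pct_below"] / fit.se["pct_below"]
            inside += abs(z) < 3
        assert inside >= 9

    def test_zero_events_raises(self):
        df = exponential_cox_data(50, 0.0, seed=3)
        df["event"] = 0
        with pytest.raises(NoEventsError):
            fit_simple(df)

    def test_log_likelihood_matches_brute_force_risk_set_formula(self):
        df = exponential_cox_data(40, np.log(2.0), seed=4)
        ev = df["event"] == 1
        assert df.loc[ev, "stop"].nunique() == ev.sum()   # no tied event times
        fit = fit_simple(df)
        ll = brute_force_log_partial_likelihood(
            fit.params.to_numpy(), df[["pct_below"]].to_numpy(),
            df["start"].to_numpy(), df["stop"].to_numpy(), df["event"].to_numpy())
        assert fit.log_likelihood == pytest.approx(ll, abs=1e-8)

    def test_left_truncated_rows_supported(self):
        df = exponential_cox_data(500, np.log(2.0), seed=5)
        df["start"] = df["stop"] * 0.3                 # delayed entry
        fit = fit_simple(df)
        ll = brute_force_log_partial_likelihood(
            fit.params.to_numpy(), df[["pct_below"]].to_numpy(),
            df["start"].to_numpy(), df["stop"].to_numpy(), df["event"].to_numpy())
        assert fit.log_likelihood == pytest.approx(ll, abs=1e-6 * abs(ll))


class TestContrasts:
    @pytest.fixture(scope="class")
    def fit(self):
        return fit_simple(exponential_cox_data(800, np.log(2.0), seed=6))

    def test_zero_delta_is_identity(self, fit):
        c = hr_contrast(fit, "pct_below", 0.0)
        assert (c.hr, c.ci_low, c.ci_high) == (1.0, 1.0, 1.0)

    def test_multiplicative_in_delta(self, fit):
        c1 = hr_contrast(fit, "pct_below", 15.0)
        c2 = hr_contrast(fit, "pct_below", 35.0)
        c3 = hr_contrast(fit, "pct_below", 50.0)
        assert c3.hr == pytest.approx(c1.hr * c2.hr, rel=1e-12)

    def test_unknown_variable_raises(self, fit):
        with pytest.raises(KeyError):
            hr_contrast(fit, "nonexistent", 1.0)

    def test_rescaling_covariate_leaves_contrasts_invariant(self):
        df = exponential_cox_data(800, np.log(2.0), seed=7)
        df["pct_below"] = df["pct_below"] * 90.0
        fit_raw = fit_simple(df)
        scaled = df.copy()
        scaled["pct_below"] = scaled["pct_below"] / 9.0
        fit_scaled = fit_simple(scaled)
        a = hr_contrast(fit_raw, "pct_below", 45.0)
        b = hr_contrast(fit_scaled, "pct_below", 5.0)
        assert a.hr == pytest.approx(b.hr, rel=1e-6)
        assert a.ci_low == pytest.approx(b.ci_low, rel=1e-6)

    def test_per_unit_recovery_from_grid(self):
        beta = 0.0157
        grid = {15: np.exp(beta * 15), 50: np.exp(beta * 50), 90: np.exp(beta * 90)}
        assert recover_per_unit_coefficient(list(grid), list(grid.values())) == pytest.approx(beta)


class TestAic:
    def test_aic_is_minus_two_ll_plus_two_k(self):
        fit = fit_simple(exponential_cox_data(300, 0.5, seed=8))
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * len(fit.params))

    def test_duplicate_fit_ties(self):
        fit = fit_simple(exponential_cox_data(300, 0.5, seed=8))
        ranking = compare_aic([fit, fit])
        assert ranking["aic"].nunique() == 1

    def test_different_risk_sets_rejected(self):
        a = fit_simple(exponential_cox_data(300, 0.5, seed=8))
        b = fit_simple(exponential_cox_data(301, 0.5, seed=8))
        with pytest.raises(ValueError, match="risk set"):
            compare_aic([a, b])

    def test_true_predictor_ranks_first_when_it_drives_hazard(self):
        wins = 0
        for seed in range(8):
            rng = np.random.default_rng(300 + seed)
            n = 600
            pct = rng.uniform(0, 100, n)
            cd4 = rng.uniform(50, 800, n)          # independent of hazard
            t = rng.exponential(1.0 / (0.005 * np.exp(0.02 * pct)))
            stop = np.minimum(t, 300.0)
            df = pd.DataFrame({"patient_id": np.arange(n).astype(str),
                               "start": 0.0, "stop": stop,
                               "event": (t <= 300.0).astype(int),
                               "pct_below": pct, "current_cd4": cd4})
            fits = [fit_cox(df, ps, adjustment=[], strata=None, outcome="death")
                    for ps in ("pct_only", "cd4_only")]
            ranking = compare_aic(fits)
            wins += ranking.iloc[0]["predictor_set"] == "pct_only"
        assert wins >= 7


class TestPredictSurvival:
    def test_monotone_from_one_and_ordered_in_exposure(self):
        df = exponential_cox_data(600, 0.02, seed=9)
        df["pct_below"] = df["pct_below"] * 60 + np.random.default_rng(9).uniform(0, 40, len(df))
        fit = fit_simple(df)
        curves = [predict_survival(fit, {"pct_below": p}) for p in (0.0, 50.0, 90.0)]
        for c in curves:
            assert c.survival[0] == 1.0
            assert np.all(np.diff(c.survival) <= 1e-12)
            assert np.all((c.survival >= 0) & (c.survival <= 1))
        s0, s50, s90 = [c.survival for c in curves]
        assert np.all(s0 >= s50 - 1e-12) and np.all(s50 >= s90 - 1e-12)

    def test_matches_closed_form_for_exponential_data(self):
        rate, beta = 0.01, np.log(2.0)
        df = exponential_cox_data(4000, beta, rate=rate, seed=10)
        fit = fit_simple(df)
        curve = predict_survival(fit, {"pct_below": 1.0})
        t = curve.times
        expected = np.exp(-rate * np.exp(beta) * t)
        mask = t < 150
        assert np.max(np.abs(curve.survival[mask] - expected[mask])) < 0.05

    def test_missing_profile_covariate_named(self):
        fit = fit_simple(exponential_cox_data(300, 0.5, seed=11))
        with pytest.raises(KeyError, match="pct_below"):
            predict_survival(fit, {})


class TestSchoenfeldTest:
    def test_matches_lifelines_on_untruncated_data(self):
        df = exponential_cox_data(500, np.log(2.0), seed=12)
        fit = fit_simple(df)
        mine = fit.ph_pvalues["pct_below"]
        cph = CoxPHFitter()
        d = df[["stop", "event", "pct_below"]]
        cph.fit(d, duration_col="stop", event_col="event")
        theirs = proportional_hazard_test(cph, d, time_transform="rank").p_value[0]
        assert mine == pytest.approx(theirs, abs=0.02)

    def test_pvalues_in_unit_interval(self, pipeline_run):
        bundle, _, _ = pipeline_run
        for o, r in bundle["outcomes"].items():
            for ps, m in r["models"].items():
                for p in m.get("ph_pvalues", {}).values():
                    assert np.isnan(p) or 0.0 <= p <= 1.0


class TestFractionalLogit:
    def test_constant_half_outcome_gives_zero_slopes(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"y": 0.5, "age": rng.normal(40, 8, 400),
                           "sex": rng.choice(["male", "female"], 400)})
        fit = fit_fractional_logit(df, "y", ["age", "sex"])
        for name, val in fit.params.items():
            if name != "const":
                assert val == pytest.approx(0.0, abs=1e-8)

    def test_binary_outcome_reduces_to_logistic_regression(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=600)
        y = (rng.random(600) < 1 / (1 + np.exp(-(0.5 + 0.8 * x)))).astype(float)
        df = pd.DataFrame({"y": y, "x": x})
        fit = fit_fractional_logit(df, "y", ["x"])
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.params["x"] == pytest.approx(ref.params[1], abs=1e-6)

    def test_recovers_known_logit_model_for_proportions(self):
        rng = np.random.default_rng(2)
        n = 4000
        x = rng.normal(size=n)
        mu = 1 / (1 + np.exp(-(-1.0 + 0.7 * x)))
        y = np.clip(mu + rng.normal(0, 0.05, n), 0, 1)
        fit = fit_fractional_logit(pd.DataFrame({"y": y, "x": x}), "y", ["x"])
        assert fit.params["x"] == pytest.approx(0.7, abs=0.07)

    def test_outcome_outside_unit_interval_rejected(self):
        df = pd.DataFrame({"y": [0.2, 1.4], "x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fit_fractional_logit(df, "y", ["x"])

    def test_odds_ratio_per_decade(self):
        rng = np.random.default_rng(3)
        n = 2000
        age = rng.normal(40, 10, n)
        mu = 1 / (1 + np.exp(-(-2.0 + 0.02 * age)))
        y = np.clip(mu + rng.normal(0, 0.05, n), 0, 1)
        fit = fit_fractional_logit(pd.DataFrame({"y": y, "age": age}), "y", ["age"])
        or10, lo, hi = fit.odds_ratio("age", 10.0)
        assert lo < np.exp(0.2) < hi


class TestEncoding:
    def test_fixed_reference_dummies(self):
        df = pd.DataFrame({"sex": ["male", "female"], "age": [30, 40]})
        X = encode_covariates(df, ["sex", "age"])
        assert list(X.columns) == ["sex_male", "age"]
        assert list(X["sex_male"]) == [1.0, 0.0]

    def test_unknown_level_rejected(self):
        df = pd.DataFrame({"sex": ["robot"]})
        with pytest.raises(ValueError, match="robot"):
            encode_covariates(df, ["sex"])
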