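import numpy as np
import pandas as pd
import pytest
from oracles import cox_score_statistic, logrank_by_hand

from nbsca import survival as sv


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survivor(self):
        curve = sv.kaplan_meier([1, 2, 3], [1, 1, 1])
        assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_censored_product_limit_hand_example(self):
        # events at 1, 3, 4; censoring at 2: S = 3/4, 3/4*1/2, then 0
        curve = sv.kaplan_meier([1, 2, 3, 4], [1, 0, 1, 1])
        assert curve.event_times.tolist() == [1, 3, 4]
        assert curve.survival == pytest.approx([3 / 4, 3 / 8, 0.0])

    def test_all_censored_is_flat(self):
        curve = sv.kaplan_meier([1, 2, 3], [0, 0, 0])
        assert curve.event_times.size == 0

    def test_random_uncensored_curves_match_empirical(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(2.0, size=200)
        curve = sv.kaplan_meier(times, np.ones(200, dtype=int))
        for t in (0.5, 1.0, 3.0):
            empirical = (times > t).mean()
            assert sv.survival_at(curve, t).estimate == pytest.approx(empirical)

    def test_tied_event_times_grouped(self):
        curve = sv.kaplan_meier([1, 1, 2], [1, 1, 1])
        assert curve.event_times.tolist() == [1, 2]
        assert curve.survival == pytest.approx([1 / 3, 0.0])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sv.kaplan_meier([], [])
        with pytest.raises(ValueError):
            sv.kaplan_meier([0.0, 1.0], [1, 1])
        with pytest.raises(ValueError):
            sv.kaplan_meier([1.0, 2.0], [1, 2])


class TestSurvivalAt:
    CURVE = sv.kaplan_meier([1, 2, 3, 4], [1, 0, 1, 1])

    def test_time_zero(self):
        point = sv.survival_at(self.CURVE, 0.0)
        assert (point.estimate, point.se) == (1.0, 0.0)

    def test_hand_computed_greenwood_se(self):
        # S(3.5) = 3/8; var = S^2 * (1/(4*3) + 1/(2*1))
        point = sv.survival_at(self.CURVE, 3.5)
        assert point.estimate == pytest.approx(0.375)
        assert point.se == pytest.approx(0.375 * np.sqrt(1 / 12 + 1 / 2), rel=1e-12)
        assert not point.extrapolated

    def test_between_steps_holds_previous_value(self):
        assert sv.survival_at(self.CURVE, 2.9).estimate == pytest.approx(0.75)

    def test_extrapolation_flagged(self):
        point = sv.survival_at(self.CURVE, 10.0)
        assert point.extrapolated
        assert point.estimate == 0.0


class TestLogrank:
    def test_identical_groups_null(self):
        times, events = [1.0, 2.0, 3.0], [1, 1, 0]
        chi2, p = sv.logrank(times, events, times, events)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_events_anywhere(self):
        chi2, p = sv.logrank([1, 2], [0, 0], [3, 4], [0, 0])
        assert (chi2, p) == (0.0, 1.0)

    def test_matches_hand_risk_set_computation(self):
        times_a, events_a = [1.0, 3.0, 5.5], [1, 1, 0]
        times_b, events_b = [2.0, 4.0, 6.0], [1, 1, 1]
        chi2, p = sv.logrank(times_a, events_a, times_b, events_b)
        oracle_chi2, oracle_p = logrank_by_hand(
            np.array(times_a), np.array(events_a),
            np.array(times_b), np.array(events_b),
        )
        assert chi2 == pytest.approx(oracle_chi2, rel=1e-9)
        assert p == pytest.approx(oracle_p, rel=1e-9)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        ta, tb = rng.exponential(1, 50), rng.exponential(2, 50)
        ea, eb = np.ones(50, int), np.ones(50, int)
        chi2_ab, _ = sv.logrank(ta, ea, tb, eb)
        chi2_ba, _ = sv.logrank(tb, eb, ta, ea)
        assert chi2_ab == pytest.approx(chi2_ba, rel=1e-9)

    def test_power_at_strong_hazard_ratio(self):
        rng = np.random.default_rng(2)
        ta = rng.exponential(1.0, 200)
        tb = rng.exponential(1 / 3.0, 200)  # true hazard ratio 3
        _, p = sv.logrank(ta, np.ones(200, int), tb, np.ones(200, int))
        assert p < 0.001


def simulate_cox_frame(rng, n, log_hr, censor_scale=4.0):
    x = rng.integers(0, 2, size=n)
    t = rng.exponential(1.0 / (0.5 * np.exp(log_hr * x)))
    c = rng.uniform(0, censor_scale, size=n)
    return pd.DataFrame({
        "time": np.minimum(t, c), "event": (t <= c).astype(int), "x": x,
    })


class TestCoxPh:
    def test_null_covariate_recovers_zero(self):
        frame = simulate_cox_frame(np.random.default_rng(3), 1000, 0.0)
        fit = sv.cox_ph(frame, covariates=["x"])
        effect = fit.effect("x")
        assert fit.converged
        assert abs(effect.coef) < 0.2
        assert effect.ci_low < 1.0 < effect.ci_high

    def test_true_hazard_ratio_recovered(self):
        frame = simulate_cox_frame(np.random.default_rng(4), 1000, np.log(2.0))
        effect = sv.cox_ph(frame, covariates=["x"]).effect("x")
        assert 1.7 < effect.hazard_ratio < 2.3
        assert effect.hazard_ratio == pytest.approx(np.exp(effect.coef), rel=1e-9)

    def test_score_test_equals_logrank_without_ties(self):
        rng = np.random.default_rng(5)
        frame = simulate_cox_frame(rng, 120, np.log(1.8))
        x = frame["x"].to_numpy()
        chi2, _ = sv.logrank(
            frame.loc[x == 0, "time"], frame.loc[x == 0, "event"],
            frame.loc[x == 1, "time"], frame.loc[x == 1, "event"],
        )
        score = cox_score_statistic(
            frame["time"].to_numpy(), frame["event"].to_numpy(), x
        )
        assert chi2 == pytest.approx(score, abs=1e-6)

    def test_constant_covariate_dropped_with_warning(self):
        frame = simulate_cox_frame(np.random.default_rng(6), 100, 0.0)
        frame["flat"] = 1
        with pytest.warns(UserWarning, match="flat"):
            fit = sv.cox_ph(frame, covariates=["x", "flat"])
        assert fit.dropped_covariates == ["flat"]
        assert [e.name for e in fit.effects] == ["x"]

    def test_separation_is_flagged_not_silent(self):
        # covariate perfectly separates events from censored subjects
        frame = pd.DataFrame({
            "time": [1, 2, 3, 4, 5, 6, 7, 8.0],
            "event": [1, 1, 1, 1, 0, 0, 0, 0],
            "x": [1, 1, 1, 1, 0, 0, 0, 0],
        })
        fit = sv.cox_ph(frame, covariates=["x"])
        assert not fit.converged

    def test_no_events_rejected(self):
        frame = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0, 1]})
        with pytest.raises(ValueError):
            sv.cox_ph(frame, covariates=["x"])


class TestPrepareAndStratify:
    def test_prepare_drops_unknowns(self, discovery_cohort):
        _, cohort = discovery_cohort
        flags = dict(zip(cohort.truth["sample_id"], cohort.truth["loss_19p"] == 1))
        frame, n_dropped = sv.prepare_survival_frame(cohort.clinical, flags, "os")
        assert n_dropped == 0
        assert len(frame) == len(cohort.clinical)
        assert set(frame.columns) >= {"time", "event", "sca_loss", "mycn", "stage4"}

    def test_stratified_survival_reports_two_groups(self, discovery_cohort):
        _, cohort = discovery_cohort
        flags = dict(zip(cohort.truth["sample_id"], cohort.truth["loss_19p"] == 1))
        frame, _ = sv.prepare_survival_frame(cohort.clinical, flags, "os")
        groups, chi2, p = sv.stratified_survival(frame)
        assert len(groups) == 2
        assert groups[0].n + groups[1].n == len(frame)
        assert 0 <= p <= 1

    def test_report_and_plot_outputs(self, tmp_path, discovery_cohort):
        _, cohort = discovery_cohort
        flags = dict(zip(cohort.truth["sample_id"], cohort.truth["loss_19p"] == 1))
        frame, _ = sv.prepare_survival_frame(cohort.clinical, flags, "os")
        groups, chi2, p = sv.stratified_survival(frame)
        cox = sv.cox_ph(frame, covariates=["sca_loss", "mycn", "stage4"])
        sv.write_survival_report(groups, chi2, p, cox, tmp_path / "surv.json")
        assert (tmp_path / "surv.json").exists()
        sv.plot_km(groups, tmp_path / "km.png")
        assert (tmp_path / "km.png").stat().st_size > 0
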