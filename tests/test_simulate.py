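import numpy as np
import pandas as pd
import pytest

from vmrloc.config import AFC_PROBE_OFFSETS_DEG, SimParams, experiment_config
from vmrloc.geometry import angle_of, radius_of
from vmrloc.kinematics import reach_features
from vmrloc.pointer import iqr
from vmrloc.schedule import TRIAL_COLUMNS, make_schedule
from vmrloc.simulate import (build_trace, simulate_afc_report,
                             simulate_experiment, simulate_learner,
                             simulate_pointer_report, simulate_trajectory)

IQR_PER_SIGMA = 1.349  # IQR of a normal distribution in units of sigma


def _mini_schedule(n_reaches, rotation_deg=45.0, target=45.0, subject="S01"):
    """Hand-built schedule: consecutive feedback reaches, constant rotation."""
    rows = []
    for i in range(n_reaches):
        rows.append(dict(
            trial_id=i, subject_id=subject, experiment_id="exp2", block=1,
            cycle_index=0, cycle_type="adaptation", cycle_length=n_reaches,
            reach_index_in_cycle=i + 1, rotation_dir="ccw", sign_dir="ccw",
            rotation_applied_deg=rotation_deg, hand_target_base_deg=target,
            hand_target_deg=target, cursor_target_deg=target, feedback=True,
            is_localization=False, localization_method="", cued=False))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _noiseless(**kw):
    base = dict(motor_noise_sd_deg=0.0, strategy_noise_sd_deg=0.0,
                extent_noise_sd_cm=0.0, strategy_mode="none")
    base.update(kw)
    return SimParams(**base)


class TestLearner:
    def test_hand_computed_recursion(self):
        """Aim-direct, A=1, B=0.1, rotation +45, no noise: the implicit
        state follows x <- 0.9 x - 4.5, i.e. -4.5 then -8.55."""
        params = _noiseless(retention_A=1.0, learning_rate_B=0.1)
        truth = simulate_learner(_mini_schedule(3), params)
        # implicit_state_deg is the state *before* each reach
        assert truth.implicit_state_deg.iloc[1] == pytest.approx(-4.5, abs=1e-12)
        assert truth.implicit_state_deg.iloc[2] == pytest.approx(-8.55, abs=1e-12)

    def test_no_learning_no_aftereffect(self):
        params = _noiseless(learning_rate_B=0.0)
        cfg = experiment_config("exp2", "pointer", n_blocks=1)
        truth = simulate_learner(make_schedule(cfg, 0), params)
        assert np.allclose(truth.implicit_state_deg, 0.0)

    def test_perfect_strategy_zero_cursor_error(self):
        """Full instructed reaiming with B=0 and no noise nulls the cursor
        error on every adaptation reach."""
        params = _noiseless(learning_rate_B=0.0, strategy_mode="instructed_full")
        cfg = experiment_config("exp1", "pointer", n_blocks=1, baseline_block=False)
        sched = make_schedule(cfg, 1)
        truth = simulate_learner(sched, params)
        adapt = truth[(sched.cycle_type == "adaptation").to_numpy()]
        assert np.allclose(adapt.cursor_error_deg, 0.0, atol=1e-12)

    def test_fixed_point(self):
        """Noiseless aim-direct learning under constant rotation converges to
        x* solving x* = A x* - B (r + x*), i.e. x* = -B r / (1 - A + B)."""
        A, B, r = 0.9, 0.2, 45.0
        params = _noiseless(retention_A=A, learning_rate_B=B)
        truth = simulate_learner(_mini_schedule(400, rotation_deg=r), params)
        x_star = -B * r / (1 - A + B)
        assert truth.implicit_state_deg.iloc[-1] == pytest.approx(x_star, abs=1e-9)

    def test_retention_only_on_no_feedback_reaches(self):
        sched = _mini_schedule(4)
        sched.loc[2, "feedback"] = False
        params = _noiseless(retention_A=0.5, learning_rate_B=0.1)
        truth = simulate_learner(sched, params)
        x2 = truth.implicit_state_deg.iloc[2]
        assert truth.implicit_state_deg.iloc[3] == pytest.approx(0.5 * x2, abs=1e-12)


class TestTrajectory:
    def test_noiseless_direction(self):
        trace = build_trace(20.0, 10.5, 400.0)
        f = reach_features(trace)
        assert f.raw_direction_deg == pytest.approx(20.0, abs=0.01)

    def test_default_speed_profile_beats_deadline(self):
        trace = build_trace(0.0, 10.5, 400.0)
        f = reach_features(trace)
        assert f.duration_to_radius_ms < 300.0

    def test_slow_preset_flagged_downstream(self):
        params = _noiseless()
        trace = simulate_trajectory(30.0, params, preset="slow")
        f = reach_features(trace)
        assert f.duration_to_radius_ms > 300.0

    def test_curved_preset_exceeds_li_threshold(self):
        params = _noiseless()
        trace = simulate_trajectory(30.0, params, preset="curved")
        f = reach_features(trace)
        assert f.linearity_index > 0.2


def _loc_trial(cycle_type="adaptation", sign_dir="ccw", method="pointer"):
    return dict(trial_id=0, subject_id="S01", cycle_type=cycle_type,
                sign_dir=sign_dir, is_localization=True,
                localization_method=method)


class TestPointerReport:
    def test_zero_bias_zero_sigma_reports_endpoint(self, rng):
        params = _noiseless(loc_bias_deg=0.0, loc_sigma_deg=1e-12,
                            radial_sigma_cm=0.0)
        trace = build_trace(25.0, 10.0, 400.0)
        rep = simulate_pointer_report(trace, _loc_trial(), params, rng)
        assert rep["reported_x_cm"] == pytest.approx(trace.xy_cm[-1, 0], abs=1e-6)
        assert rep["reported_y_cm"] == pytest.approx(trace.xy_cm[-1, 1], abs=1e-6)

    def test_cw_cycle_sign_convention(self, rng):
        """Bias 2 deg toward the cursor in a CW cycle appears as -2 raw."""
        params = _noiseless(loc_bias_deg=2.0, loc_sigma_deg=1e-12,
                            radial_sigma_cm=0.0)
        trace = build_trace(65.0, 10.0, 400.0)
        rep = simulate_pointer_report(trace, _loc_trial(sign_dir="cw"),
                                      params, rng)
        reported = np.array([rep["reported_x_cm"], rep["reported_y_cm"]])
        raw_err = angle_of(reported) - angle_of(trace.xy_cm[-1])
        assert raw_err == pytest.approx(-2.0, abs=1e-6)
        assert -raw_err == pytest.approx(2.0, abs=1e-6)  # sign-corrected

    def test_dispersion_recovery(self, rng):
        """Location/scale recovery: with sigma=5 the angular-error IQR is
        ~6.745 deg and the mean matches the bias to 3 SE at n=10000."""
        sigma, bias, n = 5.0, 1.5, 10_000
        params = _noiseless(loc_bias_deg=bias, loc_sigma_deg=sigma,
                            radial_sigma_cm=0.0)
        trace = build_trace(45.0, 10.0, 400.0)
        actual = angle_of(trace.xy_cm[-1])
        errs = np.empty(n)
        for i in range(n):
            rep = simulate_pointer_report(trace, _loc_trial(), params, rng)
            errs[i] = angle_of([rep["reported_x_cm"], rep["reported_y_cm"]]) - actual
        assert abs(errs.mean() - bias) < 3 * sigma / np.sqrt(n)
        assert iqr(errs) == pytest.approx(IQR_PER_SIGMA * sigma, rel=0.10)

    def test_wrong_trial_type_rejected(self, rng):
        trace = build_trace(45.0, 10.0, 400.0)
        with pytest.raises(ValueError):
            simulate_pointer_report(
                trace, _loc_trial(method="afc2"), _noiseless(), rng)


class TestAfcReport:
    def test_steep_slope_deterministic(self, rng):
        params = _noiseless(afc_slope_per_deg=1e6, loc_bias_deg=0.0)
        trace = build_trace(45.0, 10.0, 400.0)
        for _ in range(20):
            rep = simulate_afc_report(trace, _loc_trial(method="afc2"),
                                      params, 20.0, rng)
            assert rep["response"] == "left" and rep["correct"]

    def test_offsets_counterbalanced_per_block(self):
        cfg = experiment_config("exp2", "afc2", n_blocks=2)
        ds = simulate_experiment(cfg, SimParams(seed=3), n_subjects=1, seed=3)
        merged = ds.afc_reports.merge(
            ds.trials[["trial_id", "block", "cycle_type"]], on="trial_id")
        for _, grp in merged.groupby(["block", "cycle_type"]):
            counts = grp.probe_offset_deg.value_counts()
            assert set(counts.index) == set(AFC_PROBE_OFFSETS_DEG)
            assert counts.nunique() == 1


class TestExperimentBundle:
    def test_seeded_determinism(self):
        cfg = experiment_config("exp1", "afc2", n_blocks=1)
        a = simulate_experiment(cfg, SimParams(seed=9), n_subjects=2, seed=9)
        b = simulate_experiment(cfg, SimParams(seed=9), n_subjects=2, seed=9)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.afc_reports, b.afc_reports)

    def test_aim_direct_cursor_misses_by_rotation_minus_state(self, exp1_small):
        cfg = experiment_config("exp2", "pointer", n_blocks=1)
        ds = simulate_experiment(cfg, _noiseless(), n_subjects=1, seed=0)
        adapt = ds.trials.cycle_type == "adaptation"
        t = ds.truth[adapt.to_numpy()]
        assert np.allclose(t.cursor_error_deg, 45.0 + t.implicit_state_deg,
                           atol=1e-9)

    def test_trace_regeneration_matches_truth(self, exp1_small):
        tid = int(exp1_small.trials.trial_id.iloc[10])
        trace = exp1_small.trace(tid)
        row = exp1_small.truth.set_index("trial_id").loc[tid]
        assert angle_of(trace.xy_cm[-1]) == pytest.approx(
            row.executed_direction_deg, abs=1e-9)
        assert radius_of(trace.xy_cm[-1]) == pytest.approx(row.extent_cm, abs=1e-9)
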