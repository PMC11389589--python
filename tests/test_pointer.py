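import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from vmrloc.config import SimParams, experiment_config
from vmrloc.geometry import unit_vector
from vmrloc.pointer import (UndefinedAngleError, aftereffect_table,
                            angular_errors, compute_bias, compute_iqr, iqr,
                            performance_score, sign_correct)
from vmrloc.simulate import simulate_experiment

IQR_PER_SIGMA = 1.349


def _report_frame(actual_angles, reported_angles, radius=10.0):
    actual = radius * unit_vector(np.asarray(actual_angles, dtype=float))
    reported = radius * unit_vector(np.asarray(reported_angles, dtype=float))
    return pd.DataFrame(dict(
        trial_id=np.arange(len(actual)),
        endpoint_x_cm=actual[:, 0], endpoint_y_cm=actual[:, 1],
        reported_x_cm=reported[:, 0], reported_y_cm=reported[:, 1]))


class TestAngularErrors:
    def test_identical_positions_zero_error(self):
        df = angular_errors(_report_frame([20.0], [20.0]))
        assert df.angular_error_deg.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_definition(self):
        df = angular_errors(_report_frame([20.0], [23.0]))
        assert df.angular_error_deg.iloc[0] == pytest.approx(3.0, abs=1e-9)

    def test_batch_matches_bruteforce(self, rng):
        actual = rng.uniform(-60, 120, size=200)
        reported = actual + rng.normal(0, 10, size=200)
        df = angular_errors(_report_frame(actual, reported))
        for i in range(200):
            expected = (reported[i] - actual[i] + 180) % 360 - 180
            assert df.angular_error_deg.iloc[i] == pytest.approx(expected, abs=1e-9)

    def test_report_at_home_rejected(self):
        df = _report_frame([20.0], [20.0])
        df[["reported_x_cm", "reported_y_cm"]] = 0.0
        with pytest.raises(UndefinedAngleError):
            angular_errors(df)


class TestSignCorrect:
    def test_cw_cycles_flip(self):
        errs = pd.Series([2.0, -3.0])
        out = sign_correct(errs, pd.Series(["cw", "cw"]))
        assert out.tolist() == [-2.0, 3.0]

    def test_ccw_cycles_unchanged(self):
        errs = pd.Series([2.0, -3.0])
        assert sign_correct(errs, pd.Series(["ccw", "ccw"])).tolist() == [2.0, -3.0]

    def test_mixed_fixture_recovers_common_bias(self, rng):
        """Equal-magnitude bias toward the cursor in both rotation directions
        averages to the common bias after sign correction."""
        n = 2000
        dirs = np.where(rng.random(n) < 0.5, "ccw", "cw")
        noise = rng.normal(0, 4, n)
        raw = np.where(dirs == "ccw", 2.0 + noise, -2.0 + noise)
        corrected = sign_correct(pd.Series(raw), pd.Series(dirs))
        assert corrected.mean() == pytest.approx(2.0, abs=4 * 4 / np.sqrt(n))


def _loc_frame(errors, cycle_type="adaptation", reach_number=2, target=20.0,
               subject="S01"):
    errors = np.asarray(errors, dtype=float)
    return pd.DataFrame(dict(
        trial_id=np.arange(errors.size), subject_id=subject,
        cycle_type=cycle_type, reach_number=reach_number,
        hand_target_base_deg=target, corrected_error_deg=errors))


class TestBiasAndIqr:
    def test_constant_errors(self):
        df = _loc_frame([2.0] * 8)
        bias = compute_bias(df)
        assert (bias.bias_deg == 2.0).all()
        q = compute_iqr(df)
        assert (q.iqr_deg == 0.0).all()

    def test_known_per_bin_means(self):
        df = pd.concat([
            _loc_frame([1.0, 3.0], reach_number=2),
            _loc_frame([5.0, 7.0], reach_number=3),
        ], ignore_index=True)
        df["trial_id"] = np.arange(len(df))
        bias = compute_bias(df).set_index("reach_number").bias_deg
        assert bias["2"] == 2.0 and bias["3"] == 6.0 and bias["all"] == 4.0

    def test_normal_dispersion_closed_form(self, rng):
        df = _loc_frame(rng.normal(0.0, 5.0, size=10_000))
        q = compute_iqr(df, by_reach_number=False)
        assert q.iqr_deg.iloc[0] == pytest.approx(IQR_PER_SIGMA * 5.0, rel=0.02)

    def test_per_target_bias_subtraction_removes_mixture_inflation(self, rng):
        """Two targets with biases +-4 and equal spread: per-target
        subtraction recovers ~1.349 sigma, naive pooling is strictly larger."""
        sigma, n = 5.0, 4000
        a = _loc_frame(rng.normal(+4.0, sigma, n), target=20.0)
        b = _loc_frame(rng.normal(-4.0, sigma, n), target=65.0)
        df = pd.concat([a, b], ignore_index=True)
        df["trial_id"] = np.arange(len(df))
        q = compute_iqr(df, by_reach_number=False)
        assert q.iqr_deg.iloc[0] == pytest.approx(IQR_PER_SIGMA * sigma, rel=0.05)
        naive = iqr(df.corrected_error_deg)
        assert naive > q.iqr_deg.iloc[0] * 1.1

    def test_low_n_flag(self):
        q = compute_iqr(_loc_frame([1.0, 2.0, 3.0]), by_reach_number=False)
        assert q.low_n.all()

    @given(delta=st.floats(-20, 20), scale=st.floats(0.1, 10))
    def test_bias_shift_and_iqr_scale_equivariance(self, delta, scale):
        errs = np.array([-3.0, -1.0, 0.5, 2.0, 4.0, 7.0])
        base_bias = compute_bias(_loc_frame(errs), by_reach_number=False)
        base_iqr = compute_iqr(_loc_frame(errs), by_reach_number=False)
        shifted_bias = compute_bias(_loc_frame(errs + delta), by_reach_number=False)
        shifted_iqr = compute_iqr(_loc_frame(errs + delta), by_reach_number=False)
        assert shifted_bias.bias_deg.iloc[0] == pytest.approx(
            base_bias.bias_deg.iloc[0] + delta, abs=1e-9)
        assert shifted_iqr.iqr_deg.iloc[0] == pytest.approx(
            base_iqr.iqr_deg.iloc[0], abs=1e-9)
        scaled_iqr = compute_iqr(_loc_frame(errs * scale), by_reach_number=False)
        assert scaled_iqr.iqr_deg.iloc[0] == pytest.approx(
            base_iqr.iqr_deg.iloc[0] * scale, rel=1e-9)


class TestPerformanceScore:
    def test_printed_anchors(self):
        assert performance_score(0.0) == 100.0
        assert performance_score(10.0) == 0.0
        assert performance_score(12.0) == 0.0

    def test_linear_interpolation(self):
        assert performance_score(5.0) == 50.0
        assert performance_score(2.5) == 75.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            performance_score(-1.0)


class TestAftereffects:
    def test_no_learning_no_aftereffect(self):
        cfg = experiment_config("exp2", "pointer", n_blocks=2)
        params = SimParams(learning_rate_B=0.0, strategy_mode="none",
                           motor_noise_sd_deg=0.0, strategy_noise_sd_deg=0.0,
                           extent_noise_sd_cm=0.0, seed=2)
        ds = simulate_experiment(cfg, params, n_subjects=1, seed=2)
        feat = ds.truth[["trial_id"]].copy()
        from vmrloc.kinematics import signed_direction
        feat["direction_deg"] = [
            signed_direction(r.executed_direction_deg, t.hand_target_deg,
                             t.experiment_id, t.sign_dir)
            for r, t in zip(ds.truth.itertuples(), ds.trials.itertuples())]
        table = aftereffect_table(feat, ds.trials)
        assert np.allclose(table.aftereffect_deg, 0.0, atol=1e-9)

    def test_noiseless_aftereffect_equals_learner_state(self):
        """Without noise the first washout reach's signed direction equals
        the implicit state carried out of the adaptation cycle exactly."""
        cfg = experiment_config("exp2", "pointer", n_blocks=1)
        params = SimParams(motor_noise_sd_deg=0.0, strategy_noise_sd_deg=0.0,
                           extent_noise_sd_cm=0.0, strategy_mode="none", seed=3)
        ds = simulate_experiment(cfg, params, n_subjects=1, seed=3)
        first_wash = ds.trials[(ds.trials.cycle_type == "washout")
                               & (ds.trials.reach_index_in_cycle == 1)]
        truth = ds.truth.set_index("trial_id")
        for t in first_wash.itertuples():
            state = truth.loc[t.trial_id].implicit_state_deg
            executed = truth.loc[t.trial_id].executed_direction_deg
            # signed (CW-positive) direction = -(executed - target) = -state
            assert -(executed - t.hand_target_deg) == pytest.approx(-state,
                                                                    abs=1e-9)
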