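"""Synthetic raw data with the statistical structure the analysis assumes.

The generator stands in for human participants.  Its learner is a linear
single-state model: on every feedback reach the implicit state ``x``
(deviation of movement direction from the aim point, deg, CCW positive)
updates as ``x <- A*x - B*e`` where ``e`` is the signed error of the
cursor relative to the aim point; the final no-feedback localization reach
of each cycle applies retention only (``x <- A*x``).  Under aim-direct
instructions ``e`` coincides with the cursor error relative to the target;
under full instructed reaiming it equals rotation + state, which is what
lets implicit adaptation accumulate despite near-zero performance error
and produces aftereffects that grow with the number of rotated reaches.

Trajectories are straight minimum-jerk reaches of ~10.5 cm (stopping
shortly behind the 10 cm target) with directional motor noise.
Localization reports add a cycle-type-dependent bias toward the rotated
cursor (sign follows the cycle's rotation direction) and cycle-type-
dependent dispersion; 2AFC responses follow a logistic psychometric
function in the probe offset with the same signed bias as its PSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import AFC_PROBE_OFFSETS_DEG, ExperimentConfig, SimParams
from .geometry import angle_of, radius_of, unit_vector, wrap_angle
from .kinematics import KinematicTrace
from .schedule import make_schedule

TRUTH_COLUMNS = [
    "trial_id", "subject_id", "aim_deg", "implicit_state_deg",
    "strategy_noise_deg", "motor_noise_deg", "intended_direction_deg",
    "executed_direction_deg", "extent_cm", "duration_ms", "curvature",
    "cursor_error_deg", "endpoint_x_cm", "endpoint_y_cm",
]

POINTER_REPORT_COLUMNS = ["trial_id", "subject_id", "reported_x_cm", "reported_y_cm"]
AFC_REPORT_COLUMNS = ["trial_id", "subject_id", "probe_offset_deg", "response", "correct"]

#: Pathological trajectory presets for exercising the screening rules.
TRAJECTORY_PRESETS = {
    "slow": dict(duration_ms=900.0),          # duration to target radius > 300 ms
    "curved": dict(curvature=0.3),            # linearity index > 0.2
}


def build_trace(direction_deg: float, extent_cm: float, duration_ms: float,
                home_xy_cm=(0.0, 0.0), sample_rate_hz: float = 1000.0,
                pre_ms: float = 100.0, hold_ms: float = 150.0,
                curvature: float = 0.0,
                trial_id: Optional[int] = None) -> KinematicTrace:
    """Deterministic minimum-jerk trace for a given executed direction.

    ``curvature`` bows the path perpendicular to the home-endpoint line by
    ``curvature * extent`` at midpoint (a half-sine), so the linearity
    index of the resulting trace equals ``curvature``.
    """
    dt = 1000.0 / sample_rate_hz
    n_pre = int(round(pre_ms / dt))
    n_move = int(round(duration_ms / dt)) + 1
    n_hold = int(round(hold_ms / dt))
    u = np.linspace(0.0, 1.0, n_move)
    s = 10 * u**3 - 15 * u**4 + 6 * u**5
    along = unit_vector(direction_deg)
    perp = unit_vector(direction_deg + 90.0)
    pos = (extent_cm * s)[:, None] * along
    if curvature:
        pos = pos + (curvature * extent_cm * np.sin(np.pi * u))[:, None] * perp
    home = np.asarray(home_xy_cm, dtype=float)
    xy = np.vstack([
        np.tile(home, (n_pre, 1)),
        home + pos,
        np.tile(home + pos[-1], (n_hold, 1)),
    ])
    t = np.arange(xy.shape[0]) * dt
    return KinematicTrace(t_ms=t, xy_cm=xy, home_xy_cm=tuple(home), trial_id=trial_id)


def simulate_trajectory(intended_direction_deg: float, params: SimParams,
                        rng: Optional[np.random.Generator] = None,
                        preset: Optional[str] = None,
                        trial_id: Optional[int] = None) -> KinematicTrace:
    """One noisy reach: direction = intended + N(0, motor_noise_sd)."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    kw = dict(duration_ms=params.movement_duration_ms, curvature=0.0)
    if preset is not None:
        kw.update(TRAJECTORY_PRESETS[preset])
    direction = intended_direction_deg + rng.normal(0.0, params.motor_noise_sd_deg)
    extent = params.movement_extent_cm + rng.normal(0.0, params.extent_noise_sd_cm)
    return build_trace(direction, extent, kw["duration_ms"],
                       sample_rate_hz=params.sample_rate_hz,
                       curvature=kw["curvature"], trial_id=trial_id)


def simulate_learner(schedule: pd.DataFrame, params: SimParams,
                     rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Run the state-space learner over a single-subject schedule.

    Returns the per-trial ground truth: aim point, implicit state before
    the reach, noise draws, executed direction, cursor error, and the
    (noise-free analytic) endpoint of the executed reach.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    if schedule.subject_id.nunique() > 1:
        raise ValueError("simulate_learner expects a single-subject schedule")
    experiment_id = schedule.experiment_id.iloc[0]
    strategy = params.resolved_strategy(experiment_id)
    n = len(schedule)
    strat_noise = np.zeros(n)
    motor_noise = rng.normal(0.0, params.motor_noise_sd_deg, size=n)
    extents = params.movement_extent_cm + rng.normal(
        0.0, params.extent_noise_sd_cm, size=n)
    states = {}
    rows = np.empty((n, 5))  # state, aim, intended, executed, cursor_error
    cycle_types = schedule.cycle_type.to_numpy()
    feedback = schedule.feedback.to_numpy()
    rotations = schedule.rotation_applied_deg.to_numpy(dtype=float)
    hand_targets = schedule.hand_target_deg.to_numpy(dtype=float)
    base_targets = schedule.hand_target_base_deg.to_numpy(dtype=float)
    cursor_targets = schedule.cursor_target_deg.to_numpy(dtype=float)
    A, B = params.retention_A, params.learning_rate_B
    for i in range(n):
        key = round(float(base_targets[i]), 3) if params.per_target_states else "all"
        x = states.get(key, 0.0)
        sn = 0.0
        if strategy == "instructed_full" and cycle_types[i] == "adaptation":
            sn = rng.normal(0.0, params.strategy_noise_sd_deg)
        strat_noise[i] = sn
        aim = hand_targets[i]
        intended = aim + x + sn
        executed = intended + motor_noise[i]
        cursor_dir = executed + rotations[i]
        cursor_error = wrap_angle(cursor_dir - cursor_targets[i])
        if feedback[i]:
            drive = wrap_angle(cursor_dir - aim)   # error of the cursor vs the aim point
            states[key] = A * x - B * drive
        else:
            states[key] = A * x
        rows[i] = (x, aim, intended, executed, cursor_error)
    endpoints = extents[:, None] * unit_vector(rows[:, 3])
    return pd.DataFrame({
        "trial_id": schedule.trial_id.to_numpy(),
        "subject_id": schedule.subject_id.to_numpy(),
        "aim_deg": rows[:, 1],
        "implicit_state_deg": rows[:, 0],
        "strategy_noise_deg": strat_noise,
        "motor_noise_deg": motor_noise,
        "intended_direction_deg": rows[:, 2],
        "executed_direction_deg": rows[:, 3],
        "extent_cm": extents,
        "duration_ms": np.full(n, params.movement_duration_ms),
        "curvature": np.zeros(n),
        "cursor_error_deg": rows[:, 4],
        "endpoint_x_cm": endpoints[:, 0],
        "endpoint_y_cm": endpoints[:, 1],
    }, columns=TRUTH_COLUMNS)


def _report_sign(sign_dir: str) -> float:
    """+1 for CCW-rotation cycles, -1 for CW: the localization bias points
    toward the rotated cursor, whose offset direction follows the rotation."""
    return -1.0 if sign_dir == "cw" else 1.0


def simulate_pointer_report(trace: KinematicTrace, trial: dict, params: SimParams,
                            rng: Optional[np.random.Generator] = None) -> dict:
    """Pointer report for one localization trial, from its trace endpoint."""
    if not trial["is_localization"] or trial["localization_method"] != "pointer":
        raise ValueError("simulate_pointer_report requires a pointer localization trial")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    endpoint = trace.xy_cm[-1]
    angle = float(angle_of(endpoint, trace.home_xy_cm))
    radius = float(radius_of(endpoint, trace.home_xy_cm))
    x, y = _pointer_xy(angle, radius, str(trial["cycle_type"]),
                       str(trial["sign_dir"]), params, rng,
                       np.asarray(trace.home_xy_cm, dtype=float))
    return dict(trial_id=trial.get("trial_id"), subject_id=trial.get("subject_id"),
                reported_x_cm=x, reported_y_cm=y)


def _pointer_xy(angle_deg, radius_cm, cycle_type, sign_dir, params, rng, home):
    s = _report_sign(sign_dir)
    rep_angle = (angle_deg + s * params.loc_bias_deg[cycle_type]
                 + rng.normal(0.0, params.loc_sigma_deg[cycle_type]))
    rep_radius = radius_cm + rng.normal(0.0, params.radial_sigma_cm)
    if params.premature_press_rate and rng.random() < params.premature_press_rate:
        rep_radius = rng.uniform(0.1, 0.4) * radius_cm   # pedal pressed near the start
    xy = home + rep_radius * unit_vector(rep_angle)
    return float(xy[0]), float(xy[1])


def simulate_afc_report(trace: KinematicTrace, trial: dict, params: SimParams,
                        probe_offset_deg: float,
                        rng: Optional[np.random.Generator] = None) -> dict:
    """Left/right judgment of a probe at a signed offset from the actual hand.

    P("left") follows a logistic in (probe - shifted PSE) with the
    cycle-type slope; the PSE shift is the localization bias, signed
    toward the cursor.  "Left" corresponds to CCW along the arc.
    """
    if not trial["is_localization"] or trial["localization_method"] != "afc2":
        raise ValueError("simulate_afc_report requires a 2AFC localization trial")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    ct = str(trial["cycle_type"])
    s = _report_sign(str(trial["sign_dir"]))
    slope = params.afc_slope_per_deg[ct]
    pse = s * params.loc_bias_deg[ct]
    p_left = expit(slope * (probe_offset_deg - pse))
    response = "left" if rng.random() < p_left else "right"
    correct = (response == "left") == (probe_offset_deg > 0)
    return dict(trial_id=trial.get("trial_id"), subject_id=trial.get("subject_id"),
                probe_offset_deg=float(probe_offset_deg), response=response,
                correct=bool(correct))


@dataclass
class SimulatedDataset:
    """Bundle of one simulated run: trial table, ground truth, and reports.

    Traces are not stored; they are regenerated on demand (deterministic
    given the truth table) via :meth:`trace` or :meth:`iter_traces`.
    """

    config: ExperimentConfig
    params: SimParams
    trials: pd.DataFrame
    truth: pd.DataFrame
    pointer_reports: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=POINTER_REPORT_COLUMNS))
    afc_reports: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=AFC_REPORT_COLUMNS))
    seed: int = 0

    def trace(self, trial_id: int) -> KinematicTrace:
        if not hasattr(self, "_trace_index"):
            cols = ["executed_direction_deg", "extent_cm", "duration_ms", "curvature"]
            self._trace_index = {
                int(tid): vals for tid, *vals in
                self.truth[["trial_id", *cols]].itertuples(index=False)}
        try:
            direction, extent, duration, curvature = self._trace_index[int(trial_id)]
        except KeyError:
            raise KeyError(f"unknown trial_id {trial_id}") from None
        return build_trace(direction, extent, duration,
                           home_xy_cm=self.config.home_xy_cm,
                           sample_rate_hz=self.params.sample_rate_hz,
                           curvature=curvature, trial_id=int(trial_id))

    def iter_traces(self) -> Iterator[KinematicTrace]:
        home = self.config.home_xy_cm
        fs = self.params.sample_rate_hz
        for r in self.truth.itertuples(index=False):
            yield build_trace(r.executed_direction_deg, r.extent_cm, r.duration_ms,
                              home_xy_cm=home, sample_rate_hz=fs,
                              curvature=r.curvature, trial_id=int(r.trial_id))


def _counterbalanced_offsets(n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` probe offsets with each design offset appearing equally often.

    ``n`` must be a multiple of the number of design offsets (6); the
    block structure guarantees this (18 or 36 localizations per cycle type
    per block).
    """
    offs = np.asarray(AFC_PROBE_OFFSETS_DEG)
    if n % offs.size != 0:
        raise ValueError(f"{n} localizations cannot counterbalance {offs.size} offsets")
    out = np.tile(offs, n // offs.size)
    rng.shuffle(out)
    return out


def simulate_experiment(config: ExperimentConfig, params: SimParams,
                        n_subjects: int = 1,
                        seed: Optional[int] = None) -> SimulatedDataset:
    """Simulate a full multi-subject experiment.

    All randomness flows from a single seed through per-subject child
    generators, so a run is reproducible end to end.
    """
    config.validate()
    seed = params.seed if seed is None else int(seed)
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_subjects)
    trials_all, truth_all, pointer_rows, afc_rows = [], [], [], []
    id_offset = 0
    for si, child in enumerate(children):
        subject_id = f"S{si + 1:02d}"
        sched_seed = int(child.generate_state(1)[0] % (2**31))
        sched = make_schedule(config, sched_seed, subject_id=subject_id)
        sched["trial_id"] = sched["trial_id"] + id_offset
        id_offset += len(sched)
        rng = np.random.default_rng(child)
        truth = simulate_learner(sched, params, rng)
        loc = sched[sched.is_localization]
        if config.localization_method == "pointer":
            home = np.asarray(config.home_xy_cm, dtype=float)
            tr = truth.set_index("trial_id")
            for trial in loc.itertuples(index=False):
                r = tr.loc[trial.trial_id]
                angle = float(angle_of((r.endpoint_x_cm, r.endpoint_y_cm), home))
                radius = float(radius_of((r.endpoint_x_cm, r.endpoint_y_cm), home))
                x, y = _pointer_xy(angle, radius, trial.cycle_type, trial.sign_dir,
                                   params, rng, home)
                pointer_rows.append(dict(trial_id=trial.trial_id,
                                         subject_id=subject_id,
                                         reported_x_cm=x, reported_y_cm=y))
        else:
            for (_, _), grp in loc.groupby(["block", "cycle_type"], sort=True):
                offsets = _counterbalanced_offsets(len(grp), rng)
                for trial, off in zip(grp.itertuples(index=False), offsets):
                    ct = trial.cycle_type
                    s = _report_sign(trial.sign_dir)
                    p_left = expit(params.afc_slope_per_deg[ct]
                                   * (off - s * params.loc_bias_deg[ct]))
                    response = "left" if rng.random() < p_left else "right"
                    afc_rows.append(dict(
                        trial_id=trial.trial_id, subject_id=subject_id,
                        probe_offset_deg=float(off), response=response,
                        correct=bool((response == "left") == (off > 0))))
        trials_all.append(sched)
        truth_all.append(truth)

    trials = pd.concat(trials_all, ignore_index=True)
    truth = pd.concat(truth_all, ignore_index=True)
    pointer_reports = pd.DataFrame(pointer_rows, columns=POINTER_REPORT_COLUMNS)
    afc_reports = pd.DataFrame(afc_rows, columns=AFC_REPORT_COLUMNS)
    return SimulatedDataset(config=config, params=params, trials=trials,
                            truth=truth, pointer_reports=pointer_reports,
                            afc_reports=afc_reports, seed=seed)
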