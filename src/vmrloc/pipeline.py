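"""End-to-end orchestration: simulate/load -> features -> screen -> analyze.

``run_pipeline`` drives the full analysis on a :class:`DatasetBundle`:
kinematic feature extraction, reach and report screening, sign-corrected
bias and per-target bias-subtracted IQR (pointer), psychometric fits
(2AFC), the aftereffect table, the variability-matching control, and an
exclusion log.  Every stage output is keyed by ``trial_id`` so no trial is
lost silently; stage failures propagate with the stage name attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as pio
from . import kinematics, matching, pointer, psychometrics, screening
from .config import ConfigurationError, ExperimentConfig, SimParams
from .simulate import simulate_experiment


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """One pipeline run: either a simulation block or an input directory."""

    experiment_id: str = "exp1"
    localization_method: str = "pointer"
    input_dir: Optional[str] = None
    simulation: Optional[dict] = None        # config/params overrides + n_subjects
    out_dir: Optional[str] = None
    quartile_method: str = "linear"
    matching_floor: int = matching.DEFAULT_FLOOR
    screen_reaches: bool = True
    screen_reports: bool = True
    seed: int = 0

    def validate(self) -> None:
        if (self.input_dir is None) == (self.simulation is None):
            raise ConfigurationError(
                "exactly one of input_dir and simulation must be given")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise ConfigurationError(f"input_dir {self.input_dir} does not exist")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(**dict(d))
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    features: pd.DataFrame
    reach_screen: pd.DataFrame
    report_screen: Optional[pd.DataFrame] = None
    localization: Optional[pd.DataFrame] = None    # per-report errors (pointer)
    bias: Optional[pd.DataFrame] = None
    iqr: Optional[pd.DataFrame] = None
    scores: Optional[pd.DataFrame] = None
    psychometric: Optional[pd.DataFrame] = None
    psychometric_group: Optional[pd.DataFrame] = None
    aftereffects: Optional[pd.DataFrame] = None
    match_results: Optional[pd.DataFrame] = None
    exclusion_log: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def localization_table(bundle: pio.DatasetBundle, features: pd.DataFrame,
                       reach_kept: Optional[pd.Series] = None) -> pd.DataFrame:
    """Per-report table joining pointer reports with trial context and
    actual endpoints, with angular/radial errors computed."""
    loc_trials = bundle.trials[bundle.trials.is_localization]
    cols = ["trial_id", "subject_id", "block", "cycle_type", "cycle_length",
            "sign_dir", "hand_target_base_deg", "hand_target_deg"]
    df = bundle.pointer_reports.merge(loc_trials[cols],
                                      on=["trial_id", "subject_id"], how="inner")
    feat_cols = ["trial_id", "endpoint_x_cm", "endpoint_y_cm", "direction_deg"]
    df = df.merge(features[feat_cols], on="trial_id", how="left")
    if reach_kept is not None:
        df = df[df.trial_id.map(reach_kept).fillna(False).astype(bool)]
    home = bundle.config.home_xy_cm if bundle.config else (0.0, 0.0)
    df = pointer.angular_errors(df, home)
    df["corrected_error_deg"] = pointer.sign_correct(df["angular_error_deg"],
                                                     df["sign_dir"])
    # the localization reach is the last of its cycle: reach number = cycle length
    df["reach_number"] = df["cycle_length"].astype(int)
    return df


def run_pipeline(run: RunConfig) -> PipelineResult:
    run.validate()
    # --- load or simulate -------------------------------------------------
    try:
        if run.simulation is not None:
            sim = dict(run.simulation)
            n_subjects = int(sim.pop("n_subjects", 1))
            cfg_over = sim.pop("config", {})
            par_over = sim.pop("params", {})
            if sim:
                raise ConfigurationError(f"unknown simulation keys {sorted(sim)}")
            from .config import experiment_config
            config = experiment_config(run.experiment_id, run.localization_method,
                                       **cfg_over)
            params = SimParams(**par_over)
            dataset = simulate_experiment(config, params, n_subjects, seed=run.seed)
            bundle = pio.bundle_from_simulation(dataset)
        else:
            bundle = pio.read_dataset(run.input_dir)
    except (pio.LoadError, ConfigurationError):
        raise
    except Exception as exc:
        raise StageError("load", exc)

    result = PipelineResult(features=None, reach_screen=None)
    log = result.exclusion_log
    experiment_id = bundle.experiment_id

    # --- kinematic features ----------------------------------------------
    try:
        dist = bundle.config.movement_distance_cm if bundle.config else 10.0
        result.features = kinematics.compute_features(
            bundle.iter_traces(), bundle.trials, movement_distance_cm=dist)
    except Exception as exc:
        raise StageError("features", exc)

    # --- reach screening ---------------------------------------------------
    try:
        result.reach_screen = screening.screen_reaches(result.features, experiment_id)
        if not run.screen_reaches:
            result.reach_screen["kept"] = True
            result.reach_screen["reasons"] = ""
        kept = result.reach_screen.set_index("trial_id")["kept"]
        for reason in screening.REACH_REASONS:
            n = int(result.reach_screen[reason].sum())
            if n:
                log.append(f"reach screening: {n} reaches flagged {reason}")
        log.append(f"reach screening: kept {int(kept.sum())}/{len(kept)}")
    except Exception as exc:
        raise StageError("screen_reaches", exc)

    # --- pointer analysis --------------------------------------------------
    if len(bundle.pointer_reports):
        try:
            loc = localization_table(bundle, result.features, kept)
            rep_screen = screening.screen_pointer_reports(loc)
            if not run.screen_reports:
                rep_screen["kept"] = True
                rep_screen["reasons"] = ""
            result.report_screen = rep_screen
            for reason in screening.REPORT_REASONS:
                n = int(rep_screen[reason].sum())
                if n:
                    log.append(f"report screening: {n} reports flagged {reason}")
            loc = loc[rep_screen.set_index("trial_id")["kept"]
                      .reindex(loc.trial_id).to_numpy()]
            result.localization = loc
            by_rn = experiment_id in ("exp1", "exp2")
            result.bias = pointer.compute_bias(loc, by_reach_number=by_rn)
            result.iqr = pointer.compute_iqr(loc, by_reach_number=by_rn,
                                             quartile_method=run.quartile_method)
            dist_err = np.hypot(
                loc.reported_x_cm - loc.endpoint_x_cm,
                loc.reported_y_cm - loc.endpoint_y_cm)
            scores = loc[["trial_id", "subject_id", "block"]].copy()
            scores["score"] = pointer.performance_score(dist_err.to_numpy())
            result.scores = (scores.groupby(["subject_id", "block"])["score"]
                             .sum().reset_index())
        except Exception as exc:
            raise StageError("analyze_pointer", exc)

        # --- variability matching control ---------------------------------
        try:
            results = []
            for sid, grp in loc[loc.cycle_type.isin(["adaptation", "washout"])] \
                    .groupby("subject_id", sort=True):
                a = grp[grp.cycle_type == "adaptation"]
                w = grp[grp.cycle_type == "washout"]
                if len(a) < run.matching_floor or len(w) < run.matching_floor:
                    log.append(f"matching skipped for {sid}: too few trials")
                    continue
                results.append(matching.match_variability(
                    a, w, floor=run.matching_floor, subject_id=sid))
            if results:
                result.match_results = matching.match_results_table(results)
        except Exception as exc:
            raise StageError("match", exc)

    # --- 2AFC analysis -----------------------------------------------------
    if len(bundle.afc_reports):
        try:
            loc_trials = bundle.trials[bundle.trials.is_localization]
            cols = ["trial_id", "subject_id", "cycle_type", "sign_dir",
                    "hand_target_base_deg"]
            afc = bundle.afc_reports.merge(loc_trials[cols],
                                           on=["trial_id", "subject_id"],
                                           how="inner")
            afc = afc[afc.trial_id.map(kept).fillna(False).astype(bool)]
            result.psychometric = psychometrics.psychometric_summary(afc)
            result.psychometric_group = psychometrics.group_summary(result.psychometric)
        except Exception as exc:
            raise StageError("analyze_afc", exc)

    # --- aftereffects ------------------------------------------------------
    try:
        result.aftereffects = pointer.aftereffect_table(
            result.features, bundle.trials, kept=kept)
    except Exception as exc:
        raise StageError("aftereffects", exc)

    result.summary = summarize(result)
    if run.out_dir:
        write_result(result, run.out_dir)
    return result


def summarize(result: PipelineResult) -> dict:
    """Headline numbers: group-level bias/IQR/PSE/JND by cycle type and the
    aftereffect by preceding-reach count (medians across subjects)."""
    out: dict = {}
    if result.bias is not None:
        b = result.bias[result.bias.reach_number == "all"]
        out["bias_deg"] = {ct: float(g.bias_deg.median())
                           for ct, g in b.groupby("cycle_type")}
        q = result.iqr[result.iqr.reach_number == "all"]
        out["iqr_deg"] = {ct: float(g.iqr_deg.median())
                          for ct, g in q.groupby("cycle_type")}
    if result.psychometric is not None and len(result.psychometric):
        out["pse_deg"] = {ct: float(g.pse_deg.median())
                          for ct, g in result.psychometric.groupby("cycle_type")}
        out["jnd_deg"] = {ct: float(g.jnd_deg.median())
                          for ct, g in result.psychometric.groupby("cycle_type")}
    if result.aftereffects is not None and len(result.aftereffects):
        out["aftereffect_deg"] = {
            int(k): float(g.aftereffect_deg.mean())
            for k, g in result.aftereffects.groupby("preceding_reaches")}
    if result.match_results is not None:
        m = result.match_results
        out["matched_loc_iqr_deg"] = {
            "adaptation": float(m.loc_iqr_adaptation_deg.median()),
            "washout": float(m.loc_iqr_washout_deg.median())}
    return out


def write_result(result: PipelineResult, out_dir: str) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = dict(features=result.features, reach_screen=result.reach_screen,
                  report_screen=result.report_screen,
                  localization=result.localization, bias=result.bias,
                  iqr=result.iqr, scores=result.scores,
                  psychometric=result.psychometric,
                  psychometric_group=result.psychometric_group,
                  aftereffects=result.aftereffects,
                  match_results=result.match_results)
    for name, df in tables.items():
        if df is not None:
            df.to_csv(out / f"{name}.csv", index=False)
    with open(out / "exclusions.log", "w") as fh:
        fh.write("\n".join(result.exclusion_log) + "\n")
    import json
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
    return out
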