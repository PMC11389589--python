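"""Pointer-based localization summaries: bias, IQR, score, aftereffects.

The angular localization error of a report is the angle between reported
and actual hand position, both relative to the home position, wrapped to
(-180, 180].  In the alternating-rotation experiment (exp1) the sign of
errors from CW-rotation cycles is reversed before averaging so that
positive always points toward the rotated cursor; washout cycles inherit
the preceding adaptation cycle's direction.  Bias is the mean of
sign-corrected errors; dispersion is the interquartile range after
subtracting each target's own bias (exp1), with quartiles by linear
interpolation (config-switchable convention).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .geometry import angle_of, radius_of, wrap_angle

QUARTILE_METHODS = ("linear", "midpoint", "lower", "higher", "nearest")


class UndefinedAngleError(ValueError):
    """Reported position coincides with home; its angle is undefined."""


def iqr(values, method: str = "linear") -> float:
    """Interquartile range with an explicit quartile convention.

    ``linear`` is the type-7 convention (numpy default).  The convention
    materially affects the estimate at the per-bin sample sizes of this
    paradigm (~36 reports), hence the explicit knob.
    """
    if method not in QUARTILE_METHODS:
        raise ValueError(f"unknown quartile method {method!r}")
    v = np.asarray(values, dtype=float)
    q25, q75 = np.percentile(v, [25.0, 75.0], method=method)
    return float(q75 - q25)


def angular_errors(reports: pd.DataFrame, home_xy_cm=(0.0, 0.0)) -> pd.DataFrame:
    """Signed angular and radial error of each pointer report.

    ``reports`` must carry the reported position (``reported_x_cm``/``_y_cm``)
    and the actual endpoint (``endpoint_x_cm``/``_y_cm``).
    """
    rep = reports[["reported_x_cm", "reported_y_cm"]].to_numpy(dtype=float)
    act = reports[["endpoint_x_cm", "endpoint_y_cm"]].to_numpy(dtype=float)
    home = np.asarray(home_xy_cm, dtype=float)
    rep_r = radius_of(rep, home)
    if np.any(rep_r == 0):
        bad = reports.trial_id[rep_r == 0].tolist()
        raise UndefinedAngleError(f"reports at the home position: trials {bad}")
    err = wrap_angle(angle_of(rep, home) - angle_of(act, home))
    out = reports.copy()
    out["angular_error_deg"] = err
    out["reported_radius_cm"] = rep_r
    out["actual_extent_cm"] = radius_of(act, home)
    out["radial_error_cm"] = out["reported_radius_cm"] - out["actual_extent_cm"]
    return out


def sign_correct(errors: pd.Series, sign_dir: pd.Series) -> pd.Series:
    """Reverse the sign of errors from CW-rotation cycles (exp1 convention).

    CCW-only experiments carry ``sign_dir == 'ccw'`` throughout and pass
    through unchanged.
    """
    s = np.where(np.asarray(sign_dir) == "cw", -1.0, 1.0)
    return pd.Series(np.asarray(errors, dtype=float) * s,
                     index=getattr(errors, "index", None))


def _bins(df: pd.DataFrame, by_reach_number: bool):
    """Yield (cycle_type, reach_number, subframe) including the pooled 'all' bin."""
    for (sid, ct), grp in df.groupby(["subject_id", "cycle_type"], sort=True):
        yield sid, ct, "all", grp
        if by_reach_number:
            for rn, sub in grp.groupby("reach_number", sort=True):
                yield sid, ct, str(int(rn)), sub


def compute_bias(df: pd.DataFrame, by_reach_number: bool = True) -> pd.DataFrame:
    """Per subject x cycle type (x reach number) mean of sign-corrected errors.

    ``df`` must hold ``subject_id``, ``cycle_type``, ``reach_number`` and
    ``corrected_error_deg``.  Empty bins are absent (with a warning from
    the caller's perspective: a bin that never occurs simply yields no row).
    """
    rows = [dict(subject_id=sid, cycle_type=ct, reach_number=rn,
                 bias_deg=float(grp["corrected_error_deg"].mean()),
                 n_reports=len(grp))
            for sid, ct, rn, grp in _bins(df, by_reach_number) if len(grp)]
    return pd.DataFrame(rows)


def compute_iqr(df: pd.DataFrame, by_reach_number: bool = True,
                quartile_method: str = "linear") -> pd.DataFrame:
    """Per-bin IQR of errors after per-target bias subtraction.

    Within each subject x cycle type, the mean corrected error of each
    target (``hand_target_base_deg``) is subtracted from that target's
    errors before pooling, so that a between-target bias difference does
    not inflate the dispersion estimate.  Bins with fewer than 4 reports
    are flagged ``low_n``.
    """
    df = df.copy()
    centered = np.full(len(df), np.nan)
    for (_, _, tgt), grp in df.groupby(
            ["subject_id", "cycle_type", "hand_target_base_deg"], sort=False):
        idx = df.index.get_indexer(grp.index)
        centered[idx] = grp["corrected_error_deg"] - grp["corrected_error_deg"].mean()
    df["centered_error_deg"] = centered
    rows = []
    for sid, ct, rn, grp in _bins(df, by_reach_number):
        if not len(grp):
            continue
        rows.append(dict(subject_id=sid, cycle_type=ct, reach_number=rn,
                         iqr_deg=iqr(grp["centered_error_deg"], quartile_method),
                         n_reports=len(grp), low_n=len(grp) < 4))
    return pd.DataFrame(rows)


def performance_score(distance_cm) -> np.ndarray | float:
    """Graded pointer score: 100 points at 0 cm, 0 points at 10 cm or more.

    Interpolation between the two printed anchors is linear.  The block
    score is the sum over a block's localizations.
    """
    d = np.asarray(distance_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    score = 100.0 * np.clip(1.0 - d / 10.0, 0.0, 1.0)
    return score if score.ndim else float(score)


def aftereffect_table(features: pd.DataFrame, trials: pd.DataFrame,
                      kept: pd.Series | None = None) -> pd.DataFrame:
    """Mean signed direction of first washout reaches, by preceding cycle length.

    The first reach of each washout cycle carries the adaptation
    aftereffect; it is binned by the total length (2/3/4) of the
    immediately preceding adaptation cycle, derived from the trial table.
    """
    t = trials.copy()
    cyc = (t.drop_duplicates(["subject_id", "block", "cycle_index"])
            [["subject_id", "block", "cycle_index", "cycle_type", "cycle_length"]])
    prev = cyc.copy()
    prev["cycle_index"] = prev["cycle_index"] + 1
    merged = cyc.merge(prev, on=["subject_id", "block", "cycle_index"],
                       suffixes=("", "_prev"), how="left")
    wash = merged[(merged.cycle_type == "washout")
                  & (merged.cycle_type_prev == "adaptation")]
    key = ["subject_id", "block", "cycle_index"]
    first = t[(t.cycle_type == "washout") & (t.reach_index_in_cycle == 1)]
    first = first.merge(wash[key + ["cycle_length_prev"]], on=key, how="inner")
    feat = features[["trial_id", "direction_deg"]]
    first = first.merge(feat, on="trial_id", how="left")
    if kept is not None:
        keep_ids = set(pd.Series(kept.index[kept]) if isinstance(kept, pd.Series)
                       else kept)
        first = first[first.trial_id.isin(keep_ids)]
    rows = [dict(subject_id=sid, preceding_reaches=int(pl),
                 aftereffect_deg=float(grp.direction_deg.mean()), n=len(grp))
            for (sid, pl), grp in first.groupby(["subject_id", "cycle_length_prev"])]
    return pd.DataFrame(rows)
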