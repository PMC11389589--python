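"""Trial-rejection rules for reaches and pointer reports.

Reaches are rejected when too slow (more than 300 ms from onset to the
target-distance circle, or never crossing it), too curved (linearity
index strictly greater than 0.2), or — with two targets (exp1) — directed
at the wrong target (signed direction relative to the instructed aim
below -30 deg).  Pointer reports are rejected when the reported radial
distance is less than half the actual movement extent (premature pedal
presses) or when the radial error exceeds twice the standard deviation of
all of that subject's radial errors; the SD is computed once, before any
removal, so screening is idempotent.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

MAX_DURATION_TO_RADIUS_MS = 300.0
MAX_LINEARITY_INDEX = 0.2
WRONG_TARGET_DEG = -30.0
RADIAL_OUTLIER_SDS = 2.0
MIN_REPORTS_FOR_SD = 3

REACH_REASONS = ("too_slow", "curved", "wrong_target")
REPORT_REASONS = ("radial_low", "radial_outlier")


def _finish(df: pd.DataFrame, reason_cols) -> pd.DataFrame:
    flags = df[list(reason_cols)].to_numpy(dtype=bool)
    df["kept"] = ~flags.any(axis=1)
    df["reasons"] = [
        ";".join(r for r, f in zip(reason_cols, row) if f) for row in flags]
    return df


def screen_reaches(features: pd.DataFrame, experiment_id: str) -> pd.DataFrame:
    """Apply the kinematic rejection rules to a feature table.

    All rules are evaluated independently and every violated reason is
    recorded.  Rows with undetectable onset (``no_onset``) count as
    too_slow (they never cross the target radius).
    """
    out = features[["trial_id"]].copy()
    dur = features["duration_to_radius_ms"]
    no_onset = features["no_onset"].astype(bool) if "no_onset" in features else False
    out["too_slow"] = (dur.isna() | (dur > MAX_DURATION_TO_RADIUS_MS) | no_onset)
    out["curved"] = features["linearity_index"] > MAX_LINEARITY_INDEX
    if experiment_id == "exp1":
        out["wrong_target"] = features["direction_deg"] < WRONG_TARGET_DEG
    else:
        out["wrong_target"] = False
    return _finish(out, REACH_REASONS)


def screen_pointer_reports(reports: pd.DataFrame,
                           radial_sd: dict | None = None) -> pd.DataFrame:
    """Apply the report rejection rules, per subject.

    ``reports`` must hold ``trial_id``, ``subject_id``, ``reported_radius_cm``,
    ``actual_extent_cm`` and ``radial_error_cm``.  ``radial_sd`` can supply
    precomputed per-subject SDs (as stored in a previous result) to make
    re-screening idempotent; otherwise the SD of all of the subject's
    radial errors is computed here, before any removal.
    """
    out = reports[["trial_id", "subject_id"]].copy()
    out["radial_low"] = (reports["reported_radius_cm"]
                         < 0.5 * reports["actual_extent_cm"])
    sds = {}
    outlier = np.zeros(len(reports), dtype=bool)
    for sid, grp in reports.groupby("subject_id", sort=False):
        if radial_sd is not None and sid in radial_sd:
            sd = float(radial_sd[sid])
        elif len(grp) < MIN_REPORTS_FOR_SD:
            warnings.warn(f"subject {sid}: fewer than {MIN_REPORTS_FOR_SD} pointer "
                          "reports; radial-outlier screening skipped")
            sds[sid] = np.nan
            continue
        else:
            sd = float(grp["radial_error_cm"].std(ddof=1))
        sds[sid] = sd
        if np.isfinite(sd) and sd > 0:
            idx = reports.index.get_indexer(grp.index)
            outlier[idx] = (grp["radial_error_cm"].abs()
                            > RADIAL_OUTLIER_SDS * sd).to_numpy()
    out["radial_outlier"] = outlier
    out["radial_sd_cm"] = out["subject_id"].map(sds)
    return _finish(out, REPORT_REASONS)


def exclusion_summary(screen: pd.DataFrame, by: pd.Series | None = None) -> pd.DataFrame:
    """Counts per rejection reason (optionally per group), for the exclusion log."""
    reason_cols = [c for c in (*REACH_REASONS, *REPORT_REASONS) if c in screen.columns]
    cols = reason_cols + ["kept"]
    if by is None:
        counts = screen[cols].sum().to_frame().T
        counts.insert(0, "group", "all")
    else:
        counts = screen[cols].groupby(by.to_numpy()).sum().reset_index(names="group")
    counts["total"] = len(screen) if by is None else screen.groupby(by.to_numpy()).size().to_numpy()
    return counts
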