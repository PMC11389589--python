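"""Variability-matching control analysis.

Localization-error dispersion could in principle be inflated by the hand
itself being more variable during adaptation than washout.  This control
equates hand-position variability between the two cycle types by
iteratively removing, on every iteration, the adaptation trial whose
hand position deviates most from the adaptation median together with the
washout trial whose hand position deviates least from the washout median,
recomputing both medians and dispersions each time, and stopping at the
first iteration at which adaptation dispersion falls strictly below
washout dispersion ("just below").  Localization-error dispersion is then
recomputed on the surviving trials.

Hand position is the target-relative signed direction of the localization
reach.  Dispersion defaults to the IQR (consistent with the rest of the
package) and can be switched to the SD.  Ties in deviation are broken by
the earlier trial index, making the procedure deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pointer import iqr

DEFAULT_FLOOR = 8


@dataclass
class MatchResult:
    subject_id: str
    success: bool
    iterations: int
    removed_adaptation: int
    removed_washout: int
    remaining: dict                      # cycle_type -> surviving count
    handpos_iqr_deg: dict                # cycle_type -> post-match dispersion
    loc_iqr_deg: dict                    # cycle_type -> post-match loc-error dispersion
    kept_adaptation_ids: np.ndarray
    kept_washout_ids: np.ndarray
    trace: list = field(default_factory=list)   # per-iteration (adapt_iqr, wash_iqr)


def _dispersion(values: np.ndarray, metric: str) -> float:
    if metric == "iqr":
        return iqr(values)
    if metric == "sd":
        return float(np.std(values, ddof=1))
    raise ValueError(f"unknown variability metric {metric!r}")


def match_variability(adaptation: pd.DataFrame, washout: pd.DataFrame,
                      handpos_col: str = "direction_deg",
                      loc_col: str = "corrected_error_deg",
                      floor: int = DEFAULT_FLOOR,
                      metric: str = "iqr",
                      subject_id: str = "") -> MatchResult:
    """Equate hand-position dispersion between cycle types by trial removal.

    ``adaptation``/``washout`` hold one row per localization trial with the
    hand position (``handpos_col``) and the localization error
    (``loc_col``), indexed or keyed by ``trial_id``.  Returns removals,
    surviving counts, the per-iteration dispersion trace, and the
    localization-error dispersion recomputed on the surviving trials.
    Raises no exception when the floor is reached before the criterion;
    instead a failure result with diagnostics is returned.
    """
    for name, df in (("adaptation", adaptation), ("washout", washout)):
        if len(df) < max(floor, 2):
            raise ValueError(f"{name} set needs at least {max(floor, 2)} trials")
    a_pos = adaptation[handpos_col].to_numpy(dtype=float)
    w_pos = washout[handpos_col].to_numpy(dtype=float)
    a_ids = adaptation["trial_id"].to_numpy()
    w_ids = washout["trial_id"].to_numpy()
    a_keep = np.ones(a_pos.size, dtype=bool)
    w_keep = np.ones(w_pos.size, dtype=bool)
    trace = []
    iterations = 0
    success = False
    while True:
        a_iqr = _dispersion(a_pos[a_keep], metric)
        w_iqr = _dispersion(w_pos[w_keep], metric)
        trace.append((a_iqr, w_iqr))
        if a_iqr < w_iqr:
            success = True
            break
        if a_keep.sum() <= floor or w_keep.sum() <= floor:
            break
        # remove the most extreme adaptation trial and the most average washout trial
        a_dev = np.abs(a_pos - np.median(a_pos[a_keep]))
        a_dev[~a_keep] = -np.inf
        a_keep[int(np.argmax(a_dev))] = False
        w_dev = np.abs(w_pos - np.median(w_pos[w_keep]))
        w_dev[~w_keep] = np.inf
        w_keep[int(np.argmin(w_dev))] = False
        iterations += 1
    a_final = _dispersion(a_pos[a_keep], metric)
    w_final = _dispersion(w_pos[w_keep], metric)
    loc_a = _dispersion(adaptation[loc_col].to_numpy(dtype=float)[a_keep], metric)
    loc_w = _dispersion(washout[loc_col].to_numpy(dtype=float)[w_keep], metric)
    return MatchResult(
        subject_id=subject_id, success=success, iterations=iterations,
        removed_adaptation=int((~a_keep).sum()), removed_washout=int((~w_keep).sum()),
        remaining={"adaptation": int(a_keep.sum()), "washout": int(w_keep.sum())},
        handpos_iqr_deg={"adaptation": a_final, "washout": w_final},
        loc_iqr_deg={"adaptation": loc_a, "washout": loc_w},
        kept_adaptation_ids=a_ids[a_keep], kept_washout_ids=w_ids[w_keep],
        trace=trace)


def match_results_table(results: list[MatchResult]) -> pd.DataFrame:
    """Tidy per-subject table of matching outcomes."""
    rows = [dict(subject_id=r.subject_id, success=r.success,
                 iterations=r.iterations,
                 removed_adaptation=r.removed_adaptation,
                 removed_washout=r.removed_washout,
                 remaining_adaptation=r.remaining["adaptation"],
                 remaining_washout=r.remaining["washout"],
                 handpos_iqr_adaptation_deg=r.handpos_iqr_deg["adaptation"],
                 handpos_iqr_washout_deg=r.handpos_iqr_deg["washout"],
                 loc_iqr_adaptation_deg=r.loc_iqr_deg["adaptation"],
                 loc_iqr_washout_deg=r.loc_iqr_deg["washout"])
            for r in results]
    return pd.DataFrame(rows)
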