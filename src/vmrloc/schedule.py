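"""Trial schedules for the cycle-structured adaptation paradigm.

A block interleaves 18 adaptation and 18 washout cycles in strict
alternation.  Cycle lengths (total reaches, the final no-feedback
localization reach included) are 2, 3, or 4, with an equal number of
cycles of each length per type per block, in pseudorandom order; each
block therefore holds 108 reaches and 36 localizations.  The pointer
variant of the reaiming experiment prepends a baseline block of 36
aligned-feedback cycles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ConfigurationError, ExperimentConfig

#: Column schema of the trial table (one row per reach).
TRIAL_COLUMNS = [
    "trial_id", "subject_id", "experiment_id", "block", "cycle_index",
    "cycle_type", "cycle_length", "reach_index_in_cycle",
    "rotation_dir", "sign_dir", "rotation_applied_deg",
    "hand_target_base_deg", "hand_target_deg", "cursor_target_deg",
    "feedback", "is_localization", "localization_method", "cued",
]


def _cycle_lengths_for_block(rng: np.random.Generator, lengths, n_cycles: int):
    reps = n_cycles // len(lengths)
    out = np.repeat(np.asarray(lengths, dtype=int), reps)
    rng.shuffle(out)
    return out


def _targets_for_direction(config: ExperimentConfig, rotation_dir: str):
    """Base hand-target angle for a cycle, given its rotation direction.

    With alternating rotations and two targets, the CCW rotation is paired
    with the lower (rightmost) target and the CW rotation with the upper
    one, so that the cursor target (hand target + rotation) coincides with
    the other displayed target.
    """
    targets = config.hand_target_deg
    if len(targets) == 1:
        return targets[0]
    lo, hi = sorted(targets)
    return lo if rotation_dir == "ccw" else hi


def make_schedule(config: ExperimentConfig, seed: int,
                  subject_id: str = "S01") -> pd.DataFrame:
    """Generate the full trial sequence for one subject.

    Reproducible for a fixed ``(config, seed)``.  Target jitter is redrawn
    once per cycle, uniformly within +-``config.target_jitter_deg``, and
    shifts the hand and cursor targets together (their angular offset is
    preserved).  Washout cycles reuse the preceding adaptation cycle's
    target and inherit its rotation direction for downstream sign
    correction (column ``sign_dir``).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    rot = float(config.rotation_deg)
    rows: list[dict] = []

    def emit_cycle(block: int, cycle_index: int, cycle_type: str, length: int,
                   rotation_dir: str, sign_dir: str, base_target: float) -> None:
        jitter = rng.uniform(-config.target_jitter_deg, config.target_jitter_deg)
        hand_target = base_target + jitter
        if cycle_type == "adaptation":
            applied = rot if rotation_dir == "ccw" else -rot
            # with two targets the cursor target sits a full rotation away
            # from the hand target; with a single target the cursor is
            # simply rotated away from it (aim-direct task)
            two_targets = len(config.hand_target_deg) == 2
            cursor_target = hand_target + applied if two_targets else hand_target
        else:
            applied = 0.0
            cursor_target = hand_target
        for reach in range(1, length + 1):
            is_loc = reach == length
            rows.append(dict(
                trial_id=len(rows), subject_id=subject_id,
                experiment_id=config.experiment_id,
                block=block, cycle_index=cycle_index, cycle_type=cycle_type,
                cycle_length=length, reach_index_in_cycle=reach,
                rotation_dir=rotation_dir if cycle_type == "adaptation" else "none",
                sign_dir=sign_dir, rotation_applied_deg=applied,
                hand_target_base_deg=base_target, hand_target_deg=hand_target,
                cursor_target_deg=cursor_target,
                feedback=not is_loc, is_localization=is_loc,
                localization_method=config.localization_method if is_loc else "none",
                cued=bool(config.cue_localization and is_loc),
            ))

    n_cycles = config.cycles_per_type_per_block
    first_block = 1
    if config.baseline_block:
        lengths = _cycle_lengths_for_block(rng, config.cycle_lengths, 2 * n_cycles)
        targets = list(config.hand_target_deg)
        for ci, length in enumerate(lengths):
            emit_cycle(0, ci, "baseline", int(length), "none", "ccw",
                       targets[ci % len(targets)])

    for block in range(first_block, first_block + config.n_blocks):
        adapt_lengths = _cycle_lengths_for_block(rng, config.cycle_lengths, n_cycles)
        wash_lengths = _cycle_lengths_for_block(rng, config.cycle_lengths, n_cycles)
        if config.rotation_scheme == "alternating_cw_ccw":
            first_dir = rng.choice(["cw", "ccw"])
            dirs = [first_dir if i % 2 == 0 else
                    ("ccw" if first_dir == "cw" else "cw") for i in range(n_cycles)]
        else:
            dirs = ["ccw"] * n_cycles
        cycle_index = 0
        for i in range(n_cycles):
            adir = dirs[i]
            base = _targets_for_direction(config, adir)
            emit_cycle(block, cycle_index, "adaptation", int(adapt_lengths[i]),
                       adir, adir, base)
            cycle_index += 1
            emit_cycle(block, cycle_index, "washout", int(wash_lengths[i]),
                       "none", adir, base)
            cycle_index += 1

    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return df


def validate_schedule(trials: pd.DataFrame) -> None:
    """Structural checks on a trial table; raises ConfigurationError on violation."""
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ConfigurationError(f"trial table missing columns {sorted(missing)}")
    loc = trials[trials.is_localization]
    if not (loc.reach_index_in_cycle == loc.cycle_length).all():
        raise ConfigurationError("localization must be the final reach of its cycle")
    if loc.feedback.any():
        raise ConfigurationError("localization reaches must have feedback disabled")
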