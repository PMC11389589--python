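"""Experiment and simulator configuration.

The paradigm alternates short adaptation and washout cycles of reaching
movements under a 45 deg visuomotor rotation.  Each cycle comprises 2-4
reaches in total; the final reach of every cycle is performed without
cursor feedback and is followed by a hand-localization report (pointer or
two-alternative forced choice).

Angle convention used throughout the package: degrees, 0 deg = straight
ahead from the home position, positive counter-clockwise (CCW).  Positions
are in cm with the home position at the origin; time is in ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

CYCLE_TYPES = ("baseline", "adaptation", "washout")

#: 2AFC probe offsets relative to the actual hand position (deg).
AFC_PROBE_OFFSETS_DEG = (-20.0, -10.0, -3.33, 3.33, 10.0, 20.0)

_LN3 = math.log(3.0)


class ConfigurationError(ValueError):
    """Raised when an experiment or run configuration violates its invariants."""


@dataclass
class ExperimentConfig:
    """Design parameters of one experiment variant.

    Defaults describe the shared structure; use :func:`experiment_config`
    for the per-experiment presets (targets, jitter, rotation scheme,
    block counts).
    """

    experiment_id: str = "exp1"                    # exp1 | exp2 | exp3
    localization_method: str = "pointer"           # pointer | afc2
    n_blocks: int = 6                              # rotation blocks (baseline extra)
    cycles_per_type_per_block: int = 18
    cycle_lengths: tuple[int, ...] = (2, 3, 4)     # total reaches per cycle, localization included
    rotation_deg: float = 45.0
    rotation_scheme: str = "alternating_cw_ccw"    # alternating_cw_ccw | ccw_only
    hand_target_deg: tuple[float, ...] = (20.0, 65.0)
    cursor_target_offset_deg: float = 45.0
    target_jitter_deg: float = 7.5
    baseline_block: bool = False
    cue_localization: bool = False
    n_targets_on_localization: int = 2             # exp3 grouping factor (display only)
    home_xy_cm: tuple[float, float] = (0.0, 0.0)
    target_radius_cm: float = 0.5
    movement_distance_cm: float = 10.0

    def validate(self) -> None:
        if self.experiment_id not in ("exp1", "exp2", "exp3"):
            raise ConfigurationError(f"unknown experiment_id {self.experiment_id!r}")
        if self.localization_method not in ("pointer", "afc2"):
            raise ConfigurationError(
                f"unknown localization_method {self.localization_method!r}")
        if self.rotation_scheme not in ("alternating_cw_ccw", "ccw_only"):
            raise ConfigurationError(f"unknown rotation_scheme {self.rotation_scheme!r}")
        if not self.cycle_lengths:
            raise ConfigurationError("cycle_lengths must be non-empty")
        if self.cycles_per_type_per_block % len(self.cycle_lengths) != 0:
            raise ConfigurationError(
                "cycles_per_type_per_block must be divisible by the number of "
                f"cycle lengths ({self.cycles_per_type_per_block} vs "
                f"{len(self.cycle_lengths)})")
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks must be >= 1")
        if len(self.hand_target_deg) not in (1, 2):
            raise ConfigurationError("hand_target_deg must hold one or two targets")
        if self.rotation_scheme == "alternating_cw_ccw" and len(self.hand_target_deg) != 2:
            raise ConfigurationError(
                "alternating rotation requires two hand targets (one per direction)")
        if self.movement_distance_cm <= 0:
            raise ConfigurationError("movement_distance_cm must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentConfig":
        d = dict(d)
        for key in ("cycle_lengths", "hand_target_deg", "home_xy_cm"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def experiment_config(experiment_id: str, localization_method: str = "pointer",
                      **overrides) -> ExperimentConfig:
    """Preset :class:`ExperimentConfig` for one of the three experiments.

    exp1 (reaiming): alternating CW/CCW rotation, hand targets 20 and 65 deg,
    +-7.5 deg jitter; the pointer group adds a baseline block of aligned
    cycles, the 2AFC group runs 7 rotation blocks.
    exp2 (aim-direct): CCW-only rotation, single target at 45 deg,
    +-15 deg jitter.
    exp3 (cued localization): CCW-only, hand target 20 deg, +-15 deg jitter,
    localization trials pre-cued, pointer method, 3 blocks.
    """
    presets = {
        "exp1": dict(
            rotation_scheme="alternating_cw_ccw",
            hand_target_deg=(20.0, 65.0),
            target_jitter_deg=7.5,
            n_blocks=6 if localization_method == "pointer" else 7,
            baseline_block=localization_method == "pointer",
        ),
        "exp2": dict(
            rotation_scheme="ccw_only",
            hand_target_deg=(45.0,),
            target_jitter_deg=15.0,
            n_blocks=6 if localization_method == "pointer" else 7,
        ),
        "exp3": dict(
            rotation_scheme="ccw_only",
            hand_target_deg=(20.0,),
            target_jitter_deg=15.0,
            n_blocks=3,
            cue_localization=True,
        ),
    }
    if experiment_id not in presets:
        raise ConfigurationError(f"unknown experiment_id {experiment_id!r}")
    if experiment_id == "exp3" and localization_method != "pointer":
        raise ConfigurationError("exp3 uses the pointer method only")
    kwargs = dict(presets[experiment_id])
    kwargs.update(overrides)
    cfg = ExperimentConfig(experiment_id=experiment_id,
                           localization_method=localization_method, **kwargs)
    cfg.validate()
    return cfg


def _as_cycle_type_map(value, name: str) -> dict[str, float]:
    """Broadcast a scalar to all cycle types; validate a mapping."""
    if isinstance(value, Mapping):
        out = {ct: float(value[ct]) for ct in CYCLE_TYPES if ct in value}
        missing = set(CYCLE_TYPES) - set(out)
        if missing:
            raise ConfigurationError(f"{name} missing cycle types {sorted(missing)}")
        return out
    return {ct: float(value) for ct in CYCLE_TYPES}


@dataclass
class SimParams:
    """Parameters of the synthetic-participant generator.

    The learner is a single-state linear state-space model per hand target:
    on every feedback reach the implicit state updates as
    ``x <- A*x - B*e`` with ``e`` the cursor error relative to the aim
    point; no-feedback (localization) reaches apply retention only
    (``x <- A*x``).  Localization reports add a cycle-type-dependent bias
    toward the rotated cursor and cycle-type-dependent dispersion.

    Default report parameters are chosen to emulate the magnitudes of the
    printed group results (bias ~2 deg adaptation / 0.5 deg washout;
    dispersion giving angular-error IQRs ~10.6 / 6.0 deg; 2AFC slopes
    giving JNDs ~10.4 / 6.9 deg); they are generator defaults, not ground
    truth about any participant.
    """

    retention_A: float = 0.95
    learning_rate_B: float = 0.15
    motor_noise_sd_deg: float = 2.8
    strategy_mode: str = "auto"                    # auto | instructed_full | none
    strategy_noise_sd_deg: float = 4.0
    per_target_states: bool = True
    loc_bias_deg: dict = field(default_factory=lambda: {
        "baseline": 0.0, "adaptation": 2.0, "washout": 0.5})
    loc_sigma_deg: dict = field(default_factory=lambda: {
        "baseline": 6.78 / 1.349, "adaptation": 10.58 / 1.349,
        "washout": 6.02 / 1.349})
    radial_sigma_cm: float = 0.5
    premature_press_rate: float = 0.0
    afc_slope_per_deg: dict = field(default_factory=lambda: {
        "baseline": 2 * _LN3 / 6.87, "adaptation": 2 * _LN3 / 10.41,
        "washout": 2 * _LN3 / 6.87})
    movement_extent_cm: float = 10.5
    extent_noise_sd_cm: float = 0.3
    movement_duration_ms: float = 400.0
    sample_rate_hz: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.loc_bias_deg = _as_cycle_type_map(self.loc_bias_deg, "loc_bias_deg")
        self.loc_sigma_deg = _as_cycle_type_map(self.loc_sigma_deg, "loc_sigma_deg")
        self.afc_slope_per_deg = _as_cycle_type_map(
            self.afc_slope_per_deg, "afc_slope_per_deg")
        if not (0.0 <= self.retention_A <= 1.0):
            raise ConfigurationError("retention_A must be in [0, 1]")
        if not (0.0 <= self.learning_rate_B <= 1.0):
            raise ConfigurationError("learning_rate_B must be in [0, 1]")
        if any(s <= 0 for s in self.loc_sigma_deg.values()):
            raise ConfigurationError("loc_sigma_deg must be positive")
        if any(s <= 0 for s in self.afc_slope_per_deg.values()):
            raise ConfigurationError("afc_slope_per_deg must be positive")
        if self.strategy_mode not in ("auto", "instructed_full", "none"):
            raise ConfigurationError(f"unknown strategy_mode {self.strategy_mode!r}")

    def resolved_strategy(self, experiment_id: str) -> str:
        """Reaiming mode for an experiment: full re-aim in exp1/exp3, none in exp2."""
        if self.strategy_mode != "auto":
            return self.strategy_mode
        return "none" if experiment_id == "exp2" else "instructed_full"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimParams":
        return cls(**dict(d))
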