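"""Reach-kinematics event detection and per-trial features.

Movement onset is the first sample at which speed exceeds 5 cm/s AND the
radial distance from the home position exceeds 0.5 cm; offset is the first
time after the post-onset speed peak at which speed falls below 5 cm/s.
Movement direction is taken as the angle of the hand position relative to
home at the time of peak speed; movement extent is the radial distance of
the endpoint; curvature is summarized by the linearity index (maximum
perpendicular deviation from the home-endpoint line, divided by extent).

Speed is estimated by central differences of position without smoothing
(simulated traces are noise-free at the sample level); ``speed_filter_hz``
enables an optional low-pass Butterworth filter for recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .geometry import angle_of, radius_of, wrap_angle

ONSET_SPEED_CM_S = 5.0
ONSET_RADIUS_CM = 0.5
OFFSET_SPEED_CM_S = 5.0


class NoOnsetError(RuntimeError):
    """No sample satisfies both onset conditions."""


class UndefinedLIError(ValueError):
    """Linearity index undefined (zero movement extent)."""


@dataclass
class KinematicTrace:
    """Uniformly sampled 2-D hand path (1 kHz by default)."""

    t_ms: np.ndarray          # shape (n,)
    xy_cm: np.ndarray         # shape (n, 2)
    home_xy_cm: tuple[float, float] = (0.0, 0.0)
    trial_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.xy_cm = np.asarray(self.xy_cm, dtype=float)
        if self.t_ms.ndim != 1 or self.xy_cm.shape != (self.t_ms.size, 2):
            raise ValueError("trace arrays must have shapes (n,) and (n, 2)")

    @property
    def dt_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0]) if self.t_ms.size > 1 else np.nan

    def radius(self) -> np.ndarray:
        return radius_of(self.xy_cm, self.home_xy_cm)


@dataclass
class ReachFeatures:
    onset_ms: float
    offset_ms: float
    peak_speed_ms: float
    raw_direction_deg: float
    direction_deg: float            # sign convention applied; NaN if no trial context
    extent_cm: float
    linearity_index: float
    duration_to_radius_ms: float    # NaN if the target-distance circle is never crossed
    endpoint_xy_cm: tuple[float, float]
    offset_clamped: bool = False


def speed(trace: KinematicTrace, lowpass_hz: Optional[float] = None) -> np.ndarray:
    """Hand speed in cm/s via central differences (one-sided at the ends)."""
    xy = trace.xy_cm
    if lowpass_hz is not None:
        fs = 1000.0 / trace.dt_ms
        b, a = butter(2, lowpass_hz / (fs / 2.0))
        xy = filtfilt(b, a, xy, axis=0)
    dt_s = trace.dt_ms / 1000.0
    v = np.gradient(xy, dt_s, axis=0)
    return np.hypot(v[:, 0], v[:, 1])


def detect_onset(trace: KinematicTrace, sp: Optional[np.ndarray] = None) -> float:
    """Time (ms) of the first sample with speed > 5 cm/s AND radius > 0.5 cm."""
    if trace.t_ms.size < 2:
        raise NoOnsetError("trace too short")
    if sp is None:
        sp = speed(trace)
    ok = (sp > ONSET_SPEED_CM_S) & (trace.radius() > ONSET_RADIUS_CM)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise NoOnsetError("no sample exceeds both onset thresholds")
    return float(trace.t_ms[idx[0]])


def detect_offset(trace: KinematicTrace, onset_ms: float,
                  sp: Optional[np.ndarray] = None) -> tuple[float, bool]:
    """Offset time and a clamped flag.

    Returns the first time after the first post-onset speed peak at which
    speed drops below 5 cm/s.  If speed never drops below threshold, the
    last sample is returned with ``clamped=True``.  Starting the search at
    the first peak avoids triggering on sub-threshold jitter right at
    onset.
    """
    if onset_ms is None or not np.isfinite(onset_ms):
        raise ValueError("detect_offset requires a detected onset")
    if sp is None:
        sp = speed(trace)
    i = int(np.searchsorted(trace.t_ms, onset_ms))
    n = sp.size
    while i + 1 < n and sp[i + 1] >= sp[i]:
        i += 1
    below = np.flatnonzero(sp[i + 1:] < OFFSET_SPEED_CM_S)
    if below.size == 0:
        return float(trace.t_ms[-1]), True
    return float(trace.t_ms[i + 1 + below[0]]), False


def linearity_index(trace: KinematicTrace, onset_ms: float, offset_ms: float) -> float:
    """Max perpendicular deviation from the home-endpoint line, over extent."""
    t = trace.t_ms
    sel = (t >= onset_ms) & (t <= offset_ms)
    pts = trace.xy_cm[sel] - np.asarray(trace.home_xy_cm)
    end = pts[-1]
    extent = float(np.hypot(*end))
    if extent <= 0:
        raise UndefinedLIError("zero movement extent")
    # perpendicular distance to the home->endpoint line via the 2-D cross product
    perp = np.abs(pts[:, 0] * end[1] - pts[:, 1] * end[0]) / extent
    return float(perp.max() / extent)


def signed_direction(raw_direction_deg: float, hand_target_deg: float,
                     experiment_id: str, sign_dir: str) -> float:
    """Target-relative movement direction under the experiment's sign convention.

    In the CCW-only experiments (exp2/exp3) direction is positive clockwise.
    In exp1 it is positive in the direction of expected adaptation: CW for
    CCW-rotation cycles and CCW for CW-rotation cycles (washout cycles
    inherit the preceding adaptation cycle's direction via ``sign_dir``).
    """
    rel = wrap_angle(raw_direction_deg - hand_target_deg)
    if experiment_id == "exp1" and sign_dir == "cw":
        return rel
    return -rel


def reach_features(trace: KinematicTrace, trial: Optional[dict] = None,
                   movement_distance_cm: float = 10.0,
                   lowpass_hz: Optional[float] = None) -> ReachFeatures:
    """Extract all per-reach features from one trace.

    ``trial`` (a mapping with ``hand_target_deg``, ``experiment_id``,
    ``sign_dir``) supplies the context for the signed direction; without it
    ``direction_deg`` is NaN.
    """
    sp = speed(trace, lowpass_hz)
    onset_ms = detect_onset(trace, sp)
    offset_ms, clamped = detect_offset(trace, onset_ms, sp)
    t = trace.t_ms
    window = (t >= onset_ms) & (t <= offset_ms)
    widx = np.flatnonzero(window)
    # first global maximum of speed within [onset, offset]
    peak_i = widx[int(np.argmax(sp[widx]))]
    peak_ms = float(t[peak_i])
    raw_dir = float(angle_of(trace.xy_cm[peak_i], trace.home_xy_cm))
    end_i = widx[-1]
    endpoint = trace.xy_cm[end_i]
    extent = float(radius_of(endpoint, trace.home_xy_cm))
    li = linearity_index(trace, onset_ms, offset_ms)
    radii = trace.radius()
    after = np.flatnonzero((t >= onset_ms) & (radii >= movement_distance_cm))
    dur = float(t[after[0]] - onset_ms) if after.size else float("nan")
    if trial is not None:
        sdir = signed_direction(raw_dir, float(trial["hand_target_deg"]),
                                str(trial["experiment_id"]), str(trial["sign_dir"]))
    else:
        sdir = float("nan")
    return ReachFeatures(
        onset_ms=onset_ms, offset_ms=offset_ms, peak_speed_ms=peak_ms,
        raw_direction_deg=raw_dir, direction_deg=sdir, extent_cm=extent,
        linearity_index=li, duration_to_radius_ms=dur,
        endpoint_xy_cm=(float(endpoint[0]), float(endpoint[1])),
        offset_clamped=clamped)


FEATURE_COLUMNS = [
    "trial_id", "onset_ms", "offset_ms", "peak_speed_ms", "raw_direction_deg",
    "direction_deg", "extent_cm", "linearity_index", "duration_to_radius_ms",
    "endpoint_x_cm", "endpoint_y_cm", "offset_clamped", "no_onset",
]


def compute_features(traces: Iterable[KinematicTrace], trials: pd.DataFrame,
                     movement_distance_cm: float = 10.0,
                     lowpass_hz: Optional[float] = None) -> pd.DataFrame:
    """Feature table for a stream of traces, keyed by ``trial_id``.

    Traces whose onset cannot be detected produce a row with ``no_onset``
    set and NaN features rather than aborting the batch.
    """
    ctx_cols = ["hand_target_deg", "experiment_id", "sign_dir"]
    trial_rows = {int(tid): dict(zip(ctx_cols, vals)) for tid, *vals in
                  trials[["trial_id", *ctx_cols]].itertuples(index=False)}
    out = []
    for trace in traces:
        trial = trial_rows.get(int(trace.trial_id)) if trace.trial_id is not None else None
        row = {c: np.nan for c in FEATURE_COLUMNS}
        row["trial_id"] = trace.trial_id
        row["offset_clamped"] = False
        row["no_onset"] = False
        try:
            f = reach_features(trace, trial, movement_distance_cm, lowpass_hz)
        except NoOnsetError:
            row["no_onset"] = True
            out.append(row)
            continue
        row.update(onset_ms=f.onset_ms, offset_ms=f.offset_ms,
                   peak_speed_ms=f.peak_speed_ms,
                   raw_direction_deg=f.raw_direction_deg,
                   direction_deg=f.direction_deg, extent_cm=f.extent_cm,
                   linearity_index=f.linearity_index,
                   duration_to_radius_ms=f.duration_to_radius_ms,
                   endpoint_x_cm=f.endpoint_xy_cm[0],
                   endpoint_y_cm=f.endpoint_xy_cm[1],
                   offset_clamped=f.offset_clamped)
        out.append(row)
    return pd.DataFrame(out, columns=FEATURE_COLUMNS)
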