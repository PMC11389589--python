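"""Shared angle/position helpers.

0 deg points straight ahead (+y) from the home position; angles grow
counter-clockwise, so the unit vector at angle theta is
(-sin theta, cos theta).
"""

from __future__ import annotations

import numpy as np


def unit_vector(angle_deg):
    """Unit direction vector(s) for angle(s) in degrees CCW from straight ahead."""
    rad = np.deg2rad(np.asarray(angle_deg, dtype=float))
    return np.stack([-np.sin(rad), np.cos(rad)], axis=-1)


def angle_of(xy, home=(0.0, 0.0)):
    """Angle in degrees CCW from straight ahead of point(s) relative to home."""
    p = np.asarray(xy, dtype=float) - np.asarray(home, dtype=float)
    return np.degrees(np.arctan2(-p[..., 0], p[..., 1]))


def radius_of(xy, home=(0.0, 0.0)):
    p = np.asarray(xy, dtype=float) - np.asarray(home, dtype=float)
    return np.hypot(p[..., 0], p[..., 1])


def wrap_angle(angle_deg):
    """Wrap angle(s) to the half-open interval (-180, 180]."""
    a = np.asarray(angle_deg, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)
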