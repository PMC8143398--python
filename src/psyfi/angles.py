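"""Orientation-angle conventions and wrapping helpers.

Orientations are axial data with period 180 degrees. All public I/O is in
degrees on [0, 180); all Fisher-information math is done in radians on
[0, pi). Circular estimation uses the doubled-angle convention (2*theta,
period 360 degrees) so that standard directional statistics apply.
"""

from __future__ import annotations

import numpy as np

DEG_PERIOD = 180.0
RAD_PERIOD = np.pi


def wrap_orientation_deg(theta):
    """Reduce orientation(s) in degrees into [0, 180). Idempotent."""
    r = np.asarray(theta, dtype=float) % DEG_PERIOD
    # a tiny negative input can round to exactly the period
    return np.where(r >= DEG_PERIOD, r - DEG_PERIOD, r)[()]


def wrap_orientation_rad(theta):
    """Reduce orientation(s) in radians into [0, pi). Idempotent."""
    r = np.asarray(theta, dtype=float) % RAD_PERIOD
    return np.where(r >= RAD_PERIOD, r - RAD_PERIOD, r)[()]


def signed_diff_deg(a, b):
    """Signed circular difference a - b for orientations, in [-90, 90)."""
    return (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
            + 90.0) % DEG_PERIOD - 90.0


def signed_diff_rad(a, b):
    """Signed circular difference a - b for orientations, in [-pi/2, pi/2)."""
    return (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
            + RAD_PERIOD / 2) % RAD_PERIOD - RAD_PERIOD / 2


def deg_to_rad(theta_deg):
    return np.asarray(theta_deg, dtype=float) * (np.pi / 180.0)


def rad_to_deg(theta_rad):
    return np.asarray(theta_rad, dtype=float) * (180.0 / np.pi)
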