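"""Angle conventions shared by every stage of the pipeline.

All tissue-level orientations are *axial* quantities: an angle and its
opposite describe the same junction, division axis or polarity axis, so
everything is reduced modulo 180 degrees.

Image coordinates are pixel-centered and 0-based with x rightward and y
downward. Angles are measured counterclockwise (on screen) from +x, i.e.
the direction vector of an angle ``t`` is ``(cos t, -sin t)`` in (x, y)
image coordinates. After normalization against the sensory-organ-precursor
(SOP) cell line, 0 deg is the proximodistal (PD) wing axis and 90 deg the
anteroposterior (AP) axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReferenceAxis",
    "normalize_angle",
    "axial_angle_deg",
    "axial_direction",
    "classify_orientation",
    "axial_mean",
    "axial_difference_deg",
]


@dataclass(frozen=True)
class ReferenceAxis:
    """Image-frame angle (degrees) of the SOP-cell line, taken as 0 deg."""

    sop_angle_raw: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.sop_angle_raw):
            raise ValueError("sop_angle_raw must be finite")


def normalize_angle(raw_angle, axis: ReferenceAxis | float = 0.0):
    """Rotate an image-frame angle into the SOP frame, reduced to [0, 180).

    0 deg maps to the PD axis and 90 deg to the AP axis. Accepts scalars
    or arrays.
    """
    sop = axis.sop_angle_raw if isinstance(axis, ReferenceAxis) else float(axis)
    out = np.mod(np.asarray(raw_angle, dtype=float) - sop, 180.0)
    # mod can return 180.0 for tiny negative float noise
    out = np.where(out >= 180.0, out - 180.0, out)
    return float(out) if np.isscalar(raw_angle) or np.ndim(raw_angle) == 0 else out


def axial_angle_deg(dx, dy):
    """Axial angle in [0, 180) of a displacement in image coordinates."""
    ang = np.degrees(np.arctan2(-np.asarray(dy, float), np.asarray(dx, float)))
    out = np.mod(ang, 180.0)
    out = np.where(out >= 180.0, out - 180.0, out)
    return float(out) if np.ndim(dx) == 0 and np.ndim(dy) == 0 else out


def axial_direction(angle_deg):
    """Unit direction vector (x, y image coords) for an axial angle."""
    t = math.radians(angle_deg)
    return np.array([math.cos(t), -math.sin(t)])


def classify_orientation(angle_deg: float) -> str:
    """Classify a normalized axial angle as ``"PD"`` or ``"AP"``.

    Angles in [45, 135) are AP-oriented; the rest of [0, 180) is PD.
    Bounds are lower-inclusive / upper-exclusive.
    """
    a = float(angle_deg)
    if not (0.0 <= a < 180.0):
        raise ValueError(f"angle {a!r} outside [0, 180)")
    return "AP" if 45.0 <= a < 135.0 else "PD"


def axial_mean(angles_deg, weights=None) -> tuple[float, float]:
    """Nematic (double-angle) average of axial data.

    Returns ``(mean_angle_deg, resultant_magnitude)`` where the magnitude
    is the length of the mean double-angle vector, weighted if weights are
    given. A zero resultant reports angle 0 by convention.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float)) * 2.0
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    if a.size == 0:
        return 0.0, 0.0
    qx = float(np.mean(w * np.cos(a)))
    qy = float(np.mean(w * np.sin(a)))
    mag = math.hypot(qx, qy)
    if mag < 1e-300:
        return 0.0, 0.0
    ang = math.degrees(math.atan2(qy, qx)) / 2.0 % 180.0
    return ang, mag


def axial_difference_deg(a: float, b: float) -> float:
    """Smallest axial separation between two angles, in [0, 90]."""
    d = abs((float(a) - float(b)) % 180.0)
    return min(d, 180.0 - d)
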