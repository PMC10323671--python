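"""Clockface lateralization angle, clock position, and dysplasia grade.

With the femur resting on its posterior condyles and viewed anteriorly, the
trochlea is described on an analog clock centered on the femoral shaft axis
with 12 o'clock pointing proximally along the shaft midline.  One clock hour
spans 30 degrees.  The unsigned angle between the 12-o'clock ray and the ray
from the clock center to the patellar entry point is the lateralization
angle; severity bins are <30 (normal), [30, 46) (mild), [46, 60) (moderate),
and >=60 degrees (severe).  Lateral deviation maps clockwise toward 1-2-3
o'clock in left knees and counter-clockwise toward 11-10-9 o'clock in right
knees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .frame import AnatomicalFrame, GeometryError
from .trochlea import EntryPoint, GrooveCourse

__all__ = [
    "ClockMeasurement",
    "GradeBins",
    "DEFAULT_BINS",
    "set_clock_center",
    "lateralization_angle",
    "angle_to_clock",
    "clock_to_angle",
    "classify",
]


@dataclass(frozen=True)
class GradeBins:
    """Half-open severity bins on the lateralization angle (degrees)."""

    edges: tuple = (30.0, 46.0, 60.0)
    labels: tuple = ("normal", "mild", "moderate", "severe")

    def __post_init__(self):
        e1, e2, e3 = self.edges
        if not (0.0 < e1 < e2 < e3 < 180.0):
            raise ValueError(f"grade edges must satisfy 0 < e1 < e2 < e3 < 180, "
                             f"got {self.edges}")
        if len(self.labels) != 4:
            raise ValueError("exactly four grade labels required")


DEFAULT_BINS = GradeBins()


@dataclass
class ClockMeasurement:
    lateralization_deg: float
    signed_deg: float           # positive = lateral deviation
    clock_hour: Optional[float] = None
    grade: Optional[str] = None


def set_clock_center(frame: AnatomicalFrame, groove: GrooveCourse) -> AnatomicalFrame:
    """Place the clockface center on the shaft-axis line at the proximodistal
    level of the groove's distal terminus."""
    # derive the level from world points rather than trusting groove.s
    s_distal = float(frame.to_coords(groove.points)[:, 1].min())
    line_t, line_s, line_h = frame.to_coords(frame.shaft_line_point)[0]
    frame.clock_center = frame.from_coords(
        np.array([line_t, s_distal, line_h]))[0]
    return frame


def lateralization_angle(entry: EntryPoint, frame: AnatomicalFrame
                         ) -> ClockMeasurement:
    """Unsigned/signed angle between the 12-o'clock ray and the entry ray,
    measured in the viewing-plane projection."""
    if frame.clock_center is None:
        raise GeometryError("frame has no clock center; call set_clock_center")
    v = frame.view_axis
    d = entry.point - frame.clock_center
    d = d - np.dot(d, v) * v
    r = float(np.linalg.norm(d))
    if r < 1.0:
        raise GeometryError(
            f"entry point within {r:.2f} mm of the clockface center; "
            "angle undefined")
    cosang = float(np.clip(np.dot(d, frame.shaft_axis) / r, -1.0, 1.0))
    lat = float(np.degrees(np.arccos(cosang)))
    sign = 1.0 if float(np.dot(d, frame.bicondylar_axis)) >= 0 else -1.0
    return ClockMeasurement(lateralization_deg=lat, signed_deg=sign * lat)


def angle_to_clock(lateralization_deg: float, side: str) -> float:
    """Map a lateralization angle to a clock hour (30 degrees per hour).

    Left knees lateralize clockwise (toward 1, 2, 3 o'clock); right knees
    counter-clockwise (toward 11, 10, 9 o'clock).
    """
    if not (0.0 <= lateralization_deg <= 180.0):
        raise ValueError(f"lateralization_deg must be in [0, 180], "
                         f"got {lateralization_deg}")
    if side not in ("left", "right"):
        raise ValueError(
            "knee laterality unknown; supply --side left|right to map the "
            "clock position")
    hours = lateralization_deg / 30.0
    if side == "left":
        return hours % 12.0
    return (12.0 - hours) % 12.0


def clock_to_angle(clock_hour: float, side: str) -> float:
    """Exact inverse of :func:`angle_to_clock` on its range."""
    if not (0.0 <= clock_hour < 12.0):
        raise ValueError(f"clock_hour must be in [0, 12), got {clock_hour}")
    if side not in ("left", "right"):
        raise ValueError(
            "knee laterality unknown; supply --side left|right to map the "
            "clock position")
    deg = clock_hour * 30.0 if side == "left" else ((12.0 - clock_hour) % 12.0) * 30.0
    if deg > 180.0:
        raise ValueError(
            f"clock position {clock_hour} is on the medial half for a {side} "
            "knee; outside the lateralization range [0, 180] deg")
    return deg


def classify(lateralization_deg: float, bins: GradeBins = DEFAULT_BINS) -> str:
    """Dysplasia grade from the lateralization angle (half-open bins)."""
    if not (0.0 <= lateralization_deg <= 180.0):
        raise ValueError(f"lateralization_deg must be in [0, 180], "
                         f"got {lateralization_deg}")
    i = int(np.searchsorted(np.asarray(bins.edges), lateralization_deg,
                            side="right"))
    return bins.labels[i]
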