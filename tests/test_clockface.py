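"""Clockface conventions: angle <-> clock mapping, grading, center placement."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from trochlemetry import (AnatomicalFrame, GeometryError, GradeBins,
                          GrooveCourse, Plane, angle_to_clock, classify,
                          clock_to_angle, lateralization_angle,
                          set_clock_center)
from trochlemetry.clockface import DEFAULT_BINS
from trochlemetry.trochlea import EntryPoint


# ---------------------------------------------------------------------------
# angle -> clock hour
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("deg,side,hour", [
    (0.0, "left", 0.0),
    (0.0, "right", 0.0),
    (30.0, "left", 1.0),
    (30.0, "right", 11.0),
    (60.0, "left", 2.0),
    (60.0, "right", 10.0),
    (90.0, "left", 3.0),
    (90.0, "right", 9.0),
    (180.0, "left", 6.0),
    (180.0, "right", 6.0),
    (45.0, "left", 1.5),
    (45.0, "right", 10.5),
])
def test_angle_to_clock(deg, side, hour):
    assert angle_to_clock(deg, side) == pytest.approx(hour, abs=1e-12)


def test_one_hour_is_30_degrees():
    for side in ("left", "right"):
        h1 = angle_to_clock(30.0, side)
        h2 = angle_to_clock(60.0, side)
        assert abs(h2 - h1) == pytest.approx(1.0)


@pytest.mark.parametrize("deg,side,err", [
    (-1.0, "left", ValueError),
    (181.0, "right", ValueError),
    (30.0, "unknown", ValueError),
    (30.0, "LEFT", ValueError),
])
def test_angle_to_clock_rejects(deg, side, err):
    with pytest.raises(err):
        angle_to_clock(deg, side)


@pytest.mark.parametrize("hour,side,deg", [
    (1.0, "left", 30.0),
    (2.0, "left", 60.0),
    (11.0, "right", 30.0),
    (10.0, "right", 60.0),
    (9.0, "right", 90.0),
    (0.0, "left", 0.0),
    (6.0, "left", 180.0),
])
def test_clock_to_angle(hour, side, deg):
    assert clock_to_angle(hour, side) == pytest.approx(deg, abs=1e-12)


def test_clock_to_angle_medial_half_rejected():
    # 8 o'clock on a left knee would be a medial deviation > 180 deg
    with pytest.raises(ValueError):
        clock_to_angle(8.0, "left")
    with pytest.raises(ValueError):
        clock_to_angle(4.0, "right")
    with pytest.raises(ValueError):
        clock_to_angle(12.0, "left")  # outside [0, 12)


@given(deg=st.floats(0.0, 180.0), side=st.sampled_from(["left", "right"]))
def test_clock_round_trip(deg, side):
    assert clock_to_angle(angle_to_clock(deg, side), side) == \
        pytest.approx(deg, abs=1e-9)


# ---------------------------------------------------------------------------
# grading
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("deg,label", [
    (0.0, "normal"),
    (23.0, "normal"),
    (29.999, "normal"),
    (30.0, "mild"),
    (45.999, "mild"),
    (46.0, "moderate"),
    (56.6, "moderate"),
    (59.999, "moderate"),
    (60.0, "severe"),
    (180.0, "severe"),
])
def test_classify_bins(deg, label):
    assert classify(deg) == label


def test_classify_rejects_out_of_range():
    with pytest.raises(ValueError):
        classify(-0.1)
    with pytest.raises(ValueError):
        classify(180.1)


def test_grade_bins_validation():
    with pytest.raises(ValueError):
        GradeBins(edges=(46.0, 30.0, 60.0))
    with pytest.raises(ValueError):
        GradeBins(edges=(0.0, 46.0, 60.0))
    with pytest.raises(ValueError):
        GradeBins(labels=("a", "b", "c"))


def test_custom_bins():
    bins = GradeBins(edges=(10.0, 20.0, 30.0))
    assert classify(15.0, bins) == "mild"
    assert classify(30.0, bins) == "severe"


@given(a=st.floats(0.0, 180.0), b=st.floats(0.0, 180.0))
def test_classify_monotone(a, b):
    lo, hi = sorted((a, b))
    labels = list(DEFAULT_BINS.labels)
    assert labels.index(classify(lo)) <= labels.index(classify(hi))


# ---------------------------------------------------------------------------
# center placement and angle measurement on a hand-built frame
# ---------------------------------------------------------------------------

def _identity_frame() -> AnatomicalFrame:
    return AnatomicalFrame(
        resting_plane=Plane(point=np.zeros(3), normal=np.array([0.0, 0.0, 1.0])),
        shaft_axis=np.array([0.0, 1.0, 0.0]),
        shaft_axis_raw=np.array([0.0, 1.0, 0.0]),
        bicondylar_axis=np.array([1.0, 0.0, 0.0]),
        view_axis=np.array([0.0, 0.0, 1.0]),
        side="left",
        origin=np.zeros(3),
        shaft_line_point=np.array([0.0, 50.0, 0.0]),
        condylar_patches=(None, None),
    )


def _groove_stub() -> GrooveCourse:
    s = np.linspace(-10.0, 20.0, 16)
    pts = np.stack([np.zeros_like(s), s, np.full_like(s, 44.0)], axis=1)
    return GrooveCourse(points=pts, t=np.zeros_like(s), s=s,
                        h=np.full_like(s, 44.0))


def test_set_clock_center_on_shaft_line_at_distal_groove_level():
    frame = set_clock_center(_identity_frame(), _groove_stub())
    # on the shaft axis line (t = 0, h = 0), at the distal terminus level
    assert frame.clock_center == pytest.approx([0.0, -10.0, 0.0], abs=1e-9)


@pytest.mark.parametrize("theta", [10.0, 23.0, 45.0, 56.6, 80.0])
def test_lateralization_angle_exact(theta):
    frame = set_clock_center(_identity_frame(), _groove_stub())
    th = np.radians(theta)
    entry = EntryPoint(
        point=frame.clock_center + 35.0 * np.array([np.sin(th), np.cos(th), 0.0]),
        from_ridges=(None, None))
    cm = lateralization_angle(entry, frame)
    assert cm.lateralization_deg == pytest.approx(theta, abs=1e-9)
    assert cm.signed_deg == pytest.approx(theta, abs=1e-9)  # lateral = +


def test_medial_deviation_is_negative_signed():
    frame = set_clock_center(_identity_frame(), _groove_stub())
    entry = EntryPoint(point=frame.clock_center + np.array([-20.0, 20.0, 0.0]),
                       from_ridges=(None, None))
    cm = lateralization_angle(entry, frame)
    assert cm.signed_deg < 0
    assert cm.lateralization_deg == pytest.approx(45.0, abs=1e-9)


def test_entry_at_center_is_an_error():
    frame = set_clock_center(_identity_frame(), _groove_stub())
    entry = EntryPoint(point=frame.clock_center + np.array([0.0, 0.0, 44.0]),
                       from_ridges=(None, None))  # offset only along the view axis
    with pytest.raises(GeometryError):
        lateralization_angle(entry, frame)


def test_lateralization_requires_center():
    frame = _identity_frame()
    entry = EntryPoint(point=np.array([10.0, 10.0, 0.0]), from_ridges=(None, None))
    with pytest.raises(GeometryError):
        lateralization_angle(entry, frame)
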