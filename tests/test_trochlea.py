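"""Profile slicing, ridge/groove tracing, entry point, obliquity, spur."""

import numpy as np
import pytest

from trochlemetry import (EntryPoint, GrooveCourse, GrooveDetectionError,
                          RidgeTrace, SynthParams, TriSurface, build_frame,
                          find_entry_point, generate, groove_obliquity,
                          measure_mesh, slice_anterior_profiles)


def test_profiles_are_ordered_and_finite(knee23, measured23):
    _, audit = measured23
    profiles = audit["profiles"]
    assert len(profiles) >= 20
    s = np.array([p.s for p in profiles])
    assert np.all(np.diff(s) > 0)
    for p in profiles[::10]:
        assert np.all(np.diff(p.t) > 0)
        valid = ~np.isnan(p.h)
        if valid.any():
            assert np.all(np.isfinite(p.h[valid]))


def test_slicing_respects_mesh_resolution(knee23):
    mesh, _ = knee23
    frame = build_frame(mesh)
    few = slice_anterior_profiles(mesh, frame, n_slices=20)
    many = slice_anterior_profiles(mesh, frame, n_slices=500)
    # requesting slices finer than the mesh resolution is clamped
    assert len(many) < 500
    assert len(few) == 20
    with pytest.raises(ValueError):
        slice_anterior_profiles(mesh, frame, n_slices=10)


def test_traces_well_formed(measured23):
    _, audit = measured23
    med, lat, groove = audit["medial"], audit["lateral"], audit["groove"]
    assert med.which == "medial" and lat.which == "lateral"
    n = len(groove.s)
    assert n >= 4
    assert np.all(np.diff(groove.s) > 0)          # distal -> proximal
    assert np.all(med.t < groove.t)               # medial ridge medial of groove
    assert np.all(groove.t < lat.t)               # groove medial of lateral ridge
    assert np.all(med.prominence > 0) and np.all(lat.prominence > 0)


def test_groove_starts_near_truth(knee23, measured23):
    mesh, gt = knee23
    _, audit = measured23
    frame = audit["frame"]
    groove_t = audit["groove"].t
    truth_t = frame.to_coords(gt.groove_distal_xyz[None, :])[0, 0]
    assert abs(groove_t[0] - truth_t) < 2.0


def test_ridge_termini_near_truth(knee23, measured23):
    mesh, gt = knee23
    _, audit = measured23
    for trace, truth in zip((audit["medial"], audit["lateral"]),
                            gt.ridge_termini):
        err = float(np.linalg.norm(trace.proximal_endpoint - truth))
        assert err < 3.0, f"{trace.which} terminus off by {err:.2f} mm"


def test_entry_point_is_exact_midpoint():
    pm = np.array([[-8.0, 20.0, 50.0]])
    pl = np.array([[8.0, 24.0, 50.0]])
    med = RidgeTrace("medial", pm, np.array([4.0]), np.array([-8.0]),
                     np.array([20.0]), np.array([50.0]))
    lat = RidgeTrace("lateral", pl, np.array([4.0]), np.array([8.0]),
                     np.array([24.0]), np.array([50.0]))
    entry = find_entry_point(med, lat)
    assert np.allclose(entry.point, [0.0, 22.0, 50.0])
    assert np.allclose(entry.from_ridges[0], pm[0])
    empty = RidgeTrace("medial", np.empty((0, 3)), np.empty(0), np.empty(0),
                       np.empty(0), np.empty(0))
    with pytest.raises(GrooveDetectionError):
        find_entry_point(empty, lat)


def test_entry_point_near_truth(knee23, measured23):
    _, gt = knee23
    _, audit = measured23
    err = float(np.linalg.norm(audit["entry"].point - gt.entry_point_xyz))
    assert err < 3.0


def test_measured_obliquity_matches_radial_course(measured23, knee23):
    rec, _ = measured23
    _, gt = knee23
    # default generator course is radial, so obliquity == theta
    assert rec.obliquity_deg == pytest.approx(gt.obliquity_deg, abs=5.0)


def test_obliquity_validates_course_length(knee23):
    frame = build_frame(knee23[0])
    pts = np.zeros((3, 3))
    short = GrooveCourse(points=pts, t=np.zeros(3), s=np.arange(3.0),
                         h=np.zeros(3))
    with pytest.raises(ValueError):
        groove_obliquity(short, frame)


def test_spur_prominence_monotone_in_spur_height():
    vals = []
    for spur in (0.0, 2.0, 4.0):
        mesh, _ = generate(SynthParams(theta_deg=40.0, spur_height_mm=spur,
                                       mesh_pitch_mm=1.6, seed=21))
        rec, _ = measure_mesh(mesh)
        vals.append(rec.spur_prominence_mm)
    assert vals[0] < vals[1] < vals[2]
    # the swell amplitude should be roughly recovered on top of the baseline
    assert vals[2] - vals[0] == pytest.approx(4.0, abs=1.5)


def test_size_variation_equivariance(knee23, measured23):
    """Angles are scale-free across the anatomical size range (the absolute
    mm thresholds of the pose search assume a human distal femur, so this
    checks patient-scale variation, not arbitrary rescaling)."""
    mesh, _ = knee23
    rec0, _ = measured23
    for factor in (0.88, 1.15):
        scaled = TriSurface(mesh.vertices * factor, mesh.faces, name="scaled")
        rec1, _ = measure_mesh(scaled)
        assert rec1.lateralization_deg == pytest.approx(
            rec0.lateralization_deg, abs=1.5), factor


def test_stability_under_slice_count(knee50):
    mesh, _ = knee50
    from trochlemetry import PipelineConfig
    rec_default, _ = measure_mesh(mesh)
    rec_coarse, _ = measure_mesh(mesh, config=PipelineConfig(n_slices=40))
    assert rec_coarse.lateralization_deg == pytest.approx(
        rec_default.lateralization_deg, abs=1.0)


def test_featureless_mesh_fails_loudly():
    import trimesh
    # an ellipsoid-ish blob has no two-ridge/one-groove pattern
    blob = trimesh.creation.icosphere(subdivisions=4, radius=30.0)
    blob.apply_scale([1.6, 1.0, 0.8])
    blob.apply_translation([0.0, 0.0, 24.0])
    surf = TriSurface.from_trimesh(blob, name="blob")
    with pytest.raises(Exception) as exc_info:
        measure_mesh(surf)
    assert exc_info.type.__name__ in ("GrooveDetectionError", "GeometryError")
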