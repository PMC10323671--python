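"""Mesh loading/saving, validation invariants, and record serialization."""

import math

import numpy as np
import pytest

from trochlemetry import (FormatError, MeasurementRecord, TriSurface,
                          ValidationError, load_mesh, read_records, save_mesh,
                          write_records)


def _tetra(scale: float = 40.0) -> TriSurface:
    v = scale * np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                          [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriSurface(vertices=v, faces=f, name="tetra")


def _sorted_verts(surf: TriSurface) -> np.ndarray:
    v = np.round(surf.vertices, 6)
    return v[np.lexsort(v.T)]


@pytest.mark.parametrize("suffix", [".stl", ".ply", ".obj"])
def test_roundtrip_formats(tmp_path, suffix):
    surf = _tetra()
    path = tmp_path / f"tetra{suffix}"
    save_mesh(surf, path)
    back = load_mesh(path)
    assert np.allclose(_sorted_verts(back), _sorted_verts(surf), atol=1e-4)
    assert len(back.faces) == 4
    assert back.name == "tetra"


def test_ascii_and_binary_stl_agree(tmp_path):
    surf = _tetra()
    pa, pb = tmp_path / "a.stl", tmp_path / "b.stl"
    save_mesh(surf, pa, ascii_stl=True)
    save_mesh(surf, pb)
    assert pa.read_bytes()[:5] == b"solid"
    a, b = load_mesh(pa), load_mesh(pb)
    assert np.allclose(_sorted_verts(a), _sorted_verts(b), atol=1e-4)


def test_missing_and_unsupported_files(tmp_path):
    with pytest.raises(FormatError):
        load_mesh(tmp_path / "nope.stl")
    bad = tmp_path / "mesh.xyz"
    bad.write_text("hi")
    with pytest.raises(FormatError):
        load_mesh(bad)


def test_corrupt_stl(tmp_path):
    p = tmp_path / "garbage.stl"
    p.write_bytes(b"\x00" * 10)
    with pytest.raises(FormatError):
        load_mesh(p)


def test_auto_rescale_meters(tmp_path):
    surf = _tetra()
    meters = TriSurface(surf.vertices / 1000.0, surf.faces, name="m")
    path = tmp_path / "meters.stl"
    save_mesh(meters, path)
    back = load_mesh(path, units_hint="auto")
    assert "rescaled_m_to_mm" in back.qc_flags
    assert 20.0 <= back.bbox_diagonal <= 600.0
    # trusting the file instead must fail validation
    with pytest.raises(ValidationError):
        load_mesh(path, units_hint="mm")


def test_bad_units_hint(tmp_path):
    path = tmp_path / "t.stl"
    save_mesh(_tetra(), path)
    with pytest.raises(ValueError):
        load_mesh(path, units_hint="inches")


def test_validate_invariants():
    good = _tetra()
    good.validate()  # does not raise

    with pytest.raises(ValidationError):
        TriSurface(good.vertices[:3], good.faces[:1]).validate()

    bad_idx = TriSurface(good.vertices, good.faces.copy())
    bad_idx.faces[0, 0] = 99
    with pytest.raises(ValidationError):
        bad_idx.validate()

    with pytest.raises(ValidationError):
        TriSurface(good.vertices * 1e-3, good.faces).validate()  # too small
    with pytest.raises(ValidationError):
        TriSurface(good.vertices * 100.0, good.faces).validate()  # too large

    nonfinite = TriSurface(good.vertices.copy(), good.faces)
    nonfinite.vertices[0, 0] = np.nan
    with pytest.raises(ValidationError):
        nonfinite.validate()

    degen = TriSurface(good.vertices.copy(), good.faces.copy())
    degen.vertices[1] = degen.vertices[0]  # collapses a face to zero area
    with pytest.raises(ValidationError):
        degen.validate()


def test_transformed_is_rigid():
    surf = _tetra()
    m = np.eye(4)
    m[:3, 3] = [5.0, -2.0, 1.0]
    moved = surf.transformed(m)
    assert np.allclose(moved.vertices, surf.vertices + [5.0, -2.0, 1.0])
    assert np.array_equal(moved.faces, surf.faces)
    # original untouched
    assert np.allclose(surf.vertices.min(axis=0), 0.0)


# ---------------------------------------------------------------------------
# measurement records
# ---------------------------------------------------------------------------

def _records():
    return [
        MeasurementRecord("k1", "left", 23.4567, 0.78189, "normal",
                          21.9, 0.0, []),
        MeasurementRecord("k2", "right", 61.2345, 9.95885, "severe",
                          55.1, 3.25, ["not_watertight", "side_unknown"]),
        MeasurementRecord("k3", "unknown", float("nan"), float("nan"),
                          "failed", float("nan"), float("nan"),
                          ["failed:GeometryError:no condylar pair"]),
    ]


@pytest.mark.parametrize("fmt,suffix", [("csv", ".csv"), ("json", ".json")])
def test_record_roundtrip(tmp_path, fmt, suffix):
    recs = _records()
    path = tmp_path / f"records{suffix}"
    write_records(recs, path, format=fmt)
    back = read_records(path)
    assert len(back) == len(recs)
    for r0, r1 in zip(recs, back):
        assert r1.knee_id == r0.knee_id
        assert r1.side == r0.side
        assert r1.grade == r0.grade
        assert r1.qc_flags == r0.qc_flags
        for attr in ("lateralization_deg", "clock_hour", "obliquity_deg",
                     "spur_prominence_mm"):
            a, b = getattr(r0, attr), getattr(r1, attr)
            if math.isnan(a):
                assert math.isnan(b)
            else:
                # at least 4 significant digits survive serialization
                assert b == pytest.approx(a, rel=1e-4)


def test_write_records_rejects_empty(tmp_path):
    with pytest.raises(ValueError):
        write_records([], tmp_path / "x.csv")
    with pytest.raises(ValueError):
        write_records(_records(), tmp_path / "x.csv", format="xml")


def test_csv_column_order(tmp_path):
    path = tmp_path / "r.csv"
    write_records(_records(), path, format="csv")
    header = path.read_text().splitlines()[0]
    assert header == ("knee_id,side,lateralization_deg,clock_hour,grade,"
                      "obliquity_deg,spur_prominence_mm,qc_flags")
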