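"""Mesh and measurement-record I/O.

Surface meshes of segmented distal femurs arrive as STL/PLY/OBJ exports in
millimetres.  This module wraps :mod:`trimesh` for reading/writing, cleans
and validates the geometry, and serializes per-knee measurement records to
CSV (RFC-4180) or JSON.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "TriSurface",
    "MeasurementRecord",
    "FormatError",
    "ValidationError",
    "load_mesh",
    "save_mesh",
    "write_records",
    "read_records",
]

# Plausible size range (mm) for a segmented distal femur, used to police units.
_MIN_DIAG_MM = 20.0
_MAX_DIAG_MM = 600.0

_SUPPORTED_SUFFIXES = {".stl", ".ply", ".obj"}

RECORD_COLUMNS = (
    "knee_id",
    "side",
    "lateralization_deg",
    "clock_hour",
    "grade",
    "obliquity_deg",
    "spur_prominence_mm",
    "qc_flags",
)


class FormatError(ValueError):
    """Unreadable or unsupported mesh file format."""


class ValidationError(ValueError):
    """Mesh or record violates a structural invariant."""


@dataclass
class TriSurface:
    """A cleaned triangle surface mesh of a distal femur (millimetres)."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)

    # -- conversions -----------------------------------------------------
    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh, name: str = "") -> "TriSurface":
        return cls(vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces), name=name)

    # -- geometry helpers ------------------------------------------------
    @property
    def bbox_diagonal(self) -> float:
        lo = self.vertices.min(axis=0)
        hi = self.vertices.max(axis=0)
        return float(np.linalg.norm(hi - lo))

    @property
    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def transformed(self, matrix: np.ndarray) -> "TriSurface":
        """Return a copy under a 4x4 homogeneous transform."""
        m = self.to_trimesh()
        m.apply_transform(matrix)
        return TriSurface(np.asarray(m.vertices), np.asarray(m.faces), self.name,
                          list(self.qc_flags))

    def validate(self) -> None:
        """Raise :class:`ValidationError` naming the first failed invariant."""
        if len(self.vertices) < 4 or len(self.faces) < 4:
            raise ValidationError("mesh must have >= 4 vertices and >= 4 faces")
        if not np.all(np.isfinite(self.vertices)):
            raise ValidationError("mesh has non-finite vertex coordinates")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(self.vertices):
            raise ValidationError("face indices out of range")
        diag = self.bbox_diagonal
        if not (_MIN_DIAG_MM <= diag <= _MAX_DIAG_MM):
            raise ValidationError(
                f"bounding-box diagonal {diag:.1f} mm outside "
                f"[{_MIN_DIAG_MM:.0f}, {_MAX_DIAG_MM:.0f}] mm (unit mismatch?)"
            )
        tris = self.vertices[self.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1
        )
        if np.any(areas <= 0.0):
            raise ValidationError("mesh contains degenerate (zero-area) faces")


def _clean(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Merge duplicate vertices and drop degenerate faces."""
    mesh.merge_vertices()
    tris = mesh.triangles
    areas = 0.5 * np.linalg.norm(
        np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1
    )
    mesh.update_faces(areas > 1e-12)
    mesh.remove_unreferenced_vertices()
    return mesh


def load_mesh(path: str | Path, units_hint: str = "mm") -> TriSurface:
    """Load and clean a distal-femur surface mesh.

    Parameters
    ----------
    path : file path to an STL (binary or ASCII), PLY, or OBJ file.
    units_hint : ``"mm"`` (trust the file) or ``"auto"`` (rescale by a factor
        of 1000 if the bounding box implies metres or micrometres; rescaling
        is recorded in ``qc_flags``).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise FormatError(f"unsupported mesh format '{path.suffix}' (want STL/PLY/OBJ)")
    try:
        raw = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - surface any parser failure uniformly
        raise FormatError(f"could not read mesh from {path}: {exc}") from exc
    if not isinstance(raw, trimesh.Trimesh) or len(raw.faces) == 0:
        raise FormatError(f"{path} did not contain a triangle mesh")

    raw = _clean(raw)
    surf = TriSurface.from_trimesh(raw, name=path.stem)

    if units_hint == "auto" and len(surf.vertices) >= 4:
        diag = surf.bbox_diagonal
        if diag < _MIN_DIAG_MM and diag * 1000.0 >= _MIN_DIAG_MM:
            surf.vertices = surf.vertices * 1000.0
            surf.qc_flags.append("rescaled_m_to_mm")
        elif diag > _MAX_DIAG_MM and diag / 1000.0 <= _MAX_DIAG_MM:
            surf.vertices = surf.vertices / 1000.0
            surf.qc_flags.append("rescaled_um_to_mm")
    elif units_hint not in ("mm", "auto"):
        raise ValueError(f"units_hint must be 'mm' or 'auto', got {units_hint!r}")

    surf.validate()
    if not surf.is_watertight:
        surf.qc_flags.append("not_watertight")
    return surf


def save_mesh(surf: TriSurface, path: str | Path, ascii_stl: bool = False) -> None:
    """Write a mesh to STL/PLY/OBJ; ``ascii_stl=True`` forces the ASCII dialect."""
    path = Path(path)
    mesh = surf.to_trimesh()
    if path.suffix.lower() == ".stl" and ascii_stl:
        data = trimesh.exchange.stl.export_stl_ascii(mesh)
        path.write_text(data)
    else:
        mesh.export(str(path))


@dataclass
class MeasurementRecord:
    """Per-knee clockface measurement output."""

    knee_id: str
    side: str
    lateralization_deg: float
    clock_hour: float
    grade: str
    obliquity_deg: float
    spur_prominence_mm: float
    qc_flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _fmt(x: float) -> str:
    """Format a float with >= 4 significant digits (angles etc.)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "nan"
    return f"{float(x):.6g}"


def write_records(records: list[MeasurementRecord], path: str | Path,
                  format: str = "csv") -> None:
    """Serialize measurement records to CSV (fixed column order) or JSON."""
    if not records:
        raise ValueError("records must be non-empty")
    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(RECORD_COLUMNS)
            for r in records:
                writer.writerow([
                    r.knee_id,
                    r.side,
                    _fmt(r.lateralization_deg),
                    _fmt(r.clock_hour),
                    r.grade,
                    _fmt(r.obliquity_deg),
                    _fmt(r.spur_prominence_mm),
                    ";".join(r.qc_flags),
                ])
    elif format == "json":
        payload = []
        for r in records:
            d = r.to_dict()
            for k in ("lateralization_deg", "clock_hour", "obliquity_deg",
                      "spur_prominence_mm"):
                d[k] = float(d[k])
            payload.append(d)
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"format must be 'csv' or 'json', got {format!r}")


def _parse_float(s: str) -> float:
    return float("nan") if s == "nan" else float(s)


def read_records(path: str | Path) -> list[MeasurementRecord]:
    """Parse records written by :func:`write_records` (CSV or JSON)."""
    path = Path(path)
    records: list[MeasurementRecord] = []
    if path.suffix.lower() == ".json":
        for d in json.loads(path.read_text()):
            records.append(MeasurementRecord(**d))
        return records
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            records.append(MeasurementRecord(
                knee_id=row["knee_id"],
                side=row["side"],
                lateralization_deg=_parse_float(row["lateralization_deg"]),
                clock_hour=_parse_float(row["clock_hour"]),
                grade=row["grade"],
                obliquity_deg=_parse_float(row["obliquity_deg"]),
                spur_prominence_mm=_parse_float(row["spur_prominence_mm"]),
                qc_flags=[f for f in row["qc_flags"].split(";") if f],
            ))
    return records
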