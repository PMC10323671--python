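"""Measurement coordinate frame: resting pose, shaft axis, bicondylar axis.

The measurement convention rests the distal femur on its posterior condyles
and views it anteriorly: the resting-plane normal (pointing into the bone)
is the viewing axis, the femoral shaft's long axis projected into that plane
is the 12-o'clock direction, and the bicondylar axis runs through the two
posterior condylar contact patches, oriented medial to lateral.

The resting pose is found deterministically by a stable-pose search over
convex-hull facets (no physics): a candidate plane must support the center
of mass inside its contact polygon and carry a pair of compact contact
patches at least 15 mm apart; among valid candidates the pose whose patch
pair is most separated perpendicular to the mesh's long axis wins, which
selects the posterior-condylar pose over e.g. the anterior-face-down pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .mesh_io import TriSurface

__all__ = [
    "Plane",
    "AnatomicalFrame",
    "GeometryError",
    "compute_resting_plane",
    "estimate_shaft_axis",
    "estimate_bicondylar_axis",
    "detect_side",
    "build_frame",
]

CONTACT_TOL_MM = 0.5         # vertex-to-plane distance counting as contact
CLUSTER_GAP_MM = 5.0         # single-linkage gap separating contact patches
MIN_PATCH_SEP_MM = 15.0      # minimum condylar patch centroid separation
MAX_PATCH_EXTENT_MM = 18.0   # patches longer than this are not condyles
MIN_PATCH_COUNT = 3          # patches smaller than this are corner/edge noise
SIDE_DISTAL_SHIFT_MM = 1.0   # minimum medial-condyle distal shift to call side
COM_MARGIN_MM = 1.5          # slack for center-of-mass-in-support test
_MAX_CONTACT_SAMPLES = 2000


class GeometryError(RuntimeError):
    """Raised when the anatomy cannot be established from the mesh."""


@dataclass
class Plane:
    point: np.ndarray
    normal: np.ndarray  # unit, oriented from the plane into the bone

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.point) @ self.normal


@dataclass
class ContactPatch:
    centroid: np.ndarray
    count: int
    extent: float  # largest in-plane extent (mm)


@dataclass
class AnatomicalFrame:
    """Resting plane plus the orthonormal measurement triad.

    ``shaft_axis`` is the Gram-Schmidt projection of the raw shaft axis into
    the viewing plane (the 12-o'clock direction); the raw 3-D estimate is
    kept in ``shaft_axis_raw``.  ``bicondylar_axis`` is oriented medial to
    lateral, so the triad handedness follows laterality (right knees give a
    right-handed (view, shaft, bicondylar) triad, left knees its mirror).
    """

    resting_plane: Plane
    shaft_axis: np.ndarray
    shaft_axis_raw: np.ndarray
    bicondylar_axis: np.ndarray
    view_axis: np.ndarray
    side: str
    origin: np.ndarray               # midpoint of the condylar contact centroids
    shaft_line_point: np.ndarray     # a point on the femoral shaft axis line
    condylar_patches: tuple          # (medial ContactPatch, lateral ContactPatch)
    clock_center: Optional[np.ndarray] = None
    qc_flags: list[str] = field(default_factory=list)

    def to_coords(self, points: np.ndarray) -> np.ndarray:
        """Map world points to frame coordinates (t: mediolateral, s: shaft,
        h: anterior)."""
        basis = np.stack([self.bicondylar_axis, self.shaft_axis, self.view_axis])
        return (np.atleast_2d(points) - self.origin) @ basis.T

    def from_coords(self, tsh: np.ndarray) -> np.ndarray:
        basis = np.stack([self.bicondylar_axis, self.shaft_axis, self.view_axis])
        return self.origin + np.atleast_2d(tsh) @ basis

    def to_json_dict(self) -> dict:
        return {
            "plane_point": self.resting_plane.point.tolist(),
            "plane_normal": self.resting_plane.normal.tolist(),
            "shaft_axis": self.shaft_axis.tolist(),
            "shaft_axis_raw": self.shaft_axis_raw.tolist(),
            "bicondylar_axis": self.bicondylar_axis.tolist(),
            "view_axis": self.view_axis.tolist(),
            "side": self.side,
            "clock_center": None if self.clock_center is None
            else self.clock_center.tolist(),
            "qc_flags": list(self.qc_flags),
        }


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero-length axis")
    return v / n


def _principal_axis(points: np.ndarray) -> np.ndarray:
    c = points.mean(axis=0)
    cov = np.cov((points - c).T)
    evals, evecs = np.linalg.eigh(cov)
    return _unit(evecs[:, -1])


def _contact_points(mesh: TriSurface, plane: Plane) -> np.ndarray:
    d = plane.signed_distance(mesh.vertices)
    pts = mesh.vertices[np.abs(d) <= CONTACT_TOL_MM]
    if len(pts) > _MAX_CONTACT_SAMPLES:
        stride = int(np.ceil(len(pts) / _MAX_CONTACT_SAMPLES))
        pts = pts[::stride]
    return pts


def _cluster_patches(points: np.ndarray) -> list[ContactPatch]:
    if len(points) == 0:
        return []
    if len(points) == 1:
        return [ContactPatch(points[0].copy(), 1, 0.0)]
    labels = fcluster(linkage(points, method="single"),
                      t=CLUSTER_GAP_MM, criterion="distance")
    patches = []
    for lab in np.unique(labels):
        pts = points[labels == lab]
        extent = float(pdist(pts).max()) if len(pts) > 1 else 0.0
        patches.append(ContactPatch(pts.mean(axis=0), len(pts), extent))
    patches.sort(key=lambda p: (-p.count, tuple(np.round(p.centroid, 6))))
    return patches


def _in_plane(v: np.ndarray, normal: np.ndarray) -> np.ndarray:
    return v - np.dot(v, normal) * normal


def _condylar_pair(patches: list[ContactPatch], normal: np.ndarray,
                   long_axis: np.ndarray):
    """Best pair of compact patches >= 15 mm apart; scored by separation
    perpendicular to the mesh long axis within the plane."""
    ell = _in_plane(long_axis, normal)
    nrm = np.linalg.norm(ell)
    ell = ell / nrm if nrm > 1e-9 else None
    best = None
    candidates = [p for p in patches
                  if p.extent <= MAX_PATCH_EXTENT_MM and p.count >= MIN_PATCH_COUNT]
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            d = _in_plane(candidates[j].centroid - candidates[i].centroid, normal)
            sep = float(np.linalg.norm(d))
            if sep < MIN_PATCH_SEP_MM:
                continue
            perp = sep if ell is None else float(
                np.linalg.norm(d - np.dot(d, ell) * ell))
            if best is None or perp > best[0]:
                best = (perp, candidates[i], candidates[j])
    return best


def _com_supported(com: np.ndarray, contacts: np.ndarray, plane: Plane) -> bool:
    """Is the center of mass over the contact support region (with slack)?"""
    from shapely.geometry import MultiPoint, Point

    n = plane.normal
    u = _unit(_in_plane(np.eye(3)[np.argmin(np.abs(n))], n))
    v = np.cross(n, u)
    pts2 = np.c_[(contacts - plane.point) @ u, (contacts - plane.point) @ v]
    com2 = Point(float((com - plane.point) @ u), float((com - plane.point) @ v))
    hull = MultiPoint([tuple(p) for p in pts2]).convex_hull
    return com2.distance(hull) <= COM_MARGIN_MM


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def compute_resting_plane(mesh: TriSurface) -> Plane:
    """Supporting plane of the stable pose on the two posterior condyles."""
    tm = mesh.to_trimesh()
    hull = tm.convex_hull
    com = hull.center_mass
    long_axis = _principal_axis(mesh.vertices)

    tris = hull.triangles
    normals = hull.face_normals
    # candidate poses: COM must project close to the supporting facet, and the
    # long axis must lie roughly in the plane (excludes end-on balancing)
    origins = tris[:, 0, :]
    dist_along = np.einsum("ij,ij->i", com[None, :] - origins, normals)
    proj = com[None, :] - dist_along[:, None] * normals
    closest = trimesh.triangles.closest_point(tris, proj)
    near = np.linalg.norm(closest - proj, axis=1) <= 3.0
    flat = np.abs(normals @ long_axis) <= 0.5
    idx = np.nonzero(near & flat)[0]

    best = None
    seen = set()
    for i in idx:
        key = tuple(np.round(normals[i], 3))
        if key in seen:
            continue
        seen.add(key)
        # orient the normal into the bone
        normal = _unit(normals[i])
        plane = Plane(point=tris[i][0].copy(), normal=normal)
        d = plane.signed_distance(mesh.vertices)
        if np.median(d) < 0:
            plane.normal = -plane.normal
            d = -d
        if d.min() < -CONTACT_TOL_MM:  # not a supporting plane of the mesh
            continue
        contacts = _contact_points(mesh, plane)
        if len(contacts) < 2:
            continue
        # hull facet normals inherit vertex noise; the physical resting
        # plane is the best-fit plane of the support points, anchored so no
        # vertex lies below it
        for _ in range(2):
            if len(contacts) < 3:
                break
            c = contacts.mean(axis=0)
            rel = contacts - c
            if np.linalg.norm(rel, axis=1).max() < 1e-9:
                break
            n_new = np.linalg.svd(rel, full_matrices=False)[2][2]
            if np.dot(n_new, plane.normal) < 0:
                n_new = -n_new
            if np.dot(n_new, plane.normal) < 0.95:
                break  # degenerate (near-collinear) support; keep facet plane
            # anchor mid-band at the support centroid: anchoring at the
            # single lowest (noise-outlier) vertex would depopulate the band
            plane = Plane(point=c, normal=n_new)
            refined = _contact_points(mesh, plane)
            if len(refined) < 2:
                break
            contacts = refined
        if not _com_supported(com, contacts, plane):
            continue
        patches = _cluster_patches(contacts)
        if len(patches) < 2:
            continue
        pair = _condylar_pair(patches, plane.normal, long_axis)
        if pair is None:
            continue
        # a resting body settles into the pose with the lowest centre of
        # mass; among the stable two-patch poses this selects the posterior
        # condylar pose over anterior/edge balancing poses
        com_height = float(plane.signed_distance(com[None, :])[0])
        score = (-round(com_height, 1), round(pair[0], 3), len(contacts))
        if best is None or score > best[0]:
            best = (score, plane)
    if best is None:
        raise GeometryError(
            "no stable two-contact resting pose found; supply a manual "
            "resting plane (e.g. --plane px py pz nx ny nz)")
    return best[1]


def estimate_shaft_axis(mesh: TriSurface, plane: Plane) -> np.ndarray:
    """Principal inertia axis of the proximal 40% of the mesh, oriented
    distal to proximal."""
    verts = mesh.vertices
    ell = _principal_axis(verts)
    coord = verts @ ell
    lo, hi = coord.min(), coord.max()
    extent = hi - lo
    # the shaft end has the smaller cross-sectional spread
    spreads = []
    for sel in (coord <= lo + 0.25 * extent, coord >= hi - 0.25 * extent):
        band = verts[sel]
        rel = band - band.mean(axis=0)
        rel -= np.outer(rel @ ell, ell)
        spreads.append(float(np.sqrt((rel ** 2).sum(axis=1).mean())))
    if spreads[1] > spreads[0]:
        ell = -ell
        coord = -coord
        lo, hi = coord.min(), coord.max()
    proximal = verts[coord >= hi - 0.4 * extent]
    if len(proximal) < 50:
        raise GeometryError(
            f"proximal portion has only {len(proximal)} vertices; "
            "mesh appears truncated too distally for a shaft-axis estimate")
    axis = _principal_axis(proximal)
    if np.dot(axis, ell) < 0:
        axis = -axis
    return axis


def _condylar_patches_for(mesh: TriSurface, plane: Plane):
    contacts = _contact_points(mesh, plane)
    patches = _cluster_patches(contacts)
    pair = _condylar_pair(patches, plane.normal, _principal_axis(mesh.vertices))
    if pair is None:
        raise GeometryError(
            "contact patches not separable into two condylar clusters")
    return pair[1], pair[2]


def estimate_bicondylar_axis(mesh: TriSurface, plane: Plane,
                             shaft_axis: Optional[np.ndarray] = None,
                             side: str = "unknown") -> np.ndarray:
    """Unit vector through the condylar contact centroids, orthogonalized
    against the shaft axis, oriented medial to lateral when ``side`` is known."""
    p1, p2 = _condylar_patches_for(mesh, plane)
    d = _unit(p2.centroid - p1.centroid)
    if shaft_axis is not None:
        d = _unit(d - np.dot(d, shaft_axis) * shaft_axis)
    if side in ("left", "right") and shaft_axis is not None:
        d = _orient_bicondylar(d, plane.normal, shaft_axis, side)
    return d


def _orient_bicondylar(d: np.ndarray, view: np.ndarray, shaft: np.ndarray,
                       side: str) -> np.ndarray:
    """Flip ``d`` so it points medial -> lateral for the given side.

    Convention: for a right knee the (view, shaft, medial->lateral) triad is
    right-handed; for a left knee it is left-handed (mirror image).
    """
    handed = float(np.dot(view, np.cross(shaft, d)))
    want_positive = side == "right"
    if (handed > 0) != want_positive:
        d = -d
    return d


def detect_side(mesh: TriSurface, plane: Plane,
                shaft_axis: np.ndarray) -> str:
    """Heuristic laterality from condylar contact asymmetry.

    The medial condyle's contact patch sits farther distally (and is larger);
    returns ``"unknown"`` when the asymmetry signal is below threshold.
    """
    try:
        p1, p2 = _condylar_patches_for(mesh, plane)
    except GeometryError:
        return "unknown"
    s1 = float(p1.centroid @ shaft_axis)
    s2 = float(p2.centroid @ shaft_axis)
    if abs(s1 - s2) >= SIDE_DISTAL_SHIFT_MM:
        medial, lateral = (p1, p2) if s1 < s2 else (p2, p1)
    elif max(p1.count, p2.count) >= 1.2 * min(p1.count, p2.count) and \
            min(p1.count, p2.count) > 0:
        medial, lateral = (p1, p2) if p1.count > p2.count else (p2, p1)
    else:
        return "unknown"
    d = _unit(lateral.centroid - medial.centroid)
    d = _unit(d - np.dot(d, plane.normal) * plane.normal)
    handed = float(np.dot(plane.normal, np.cross(shaft_axis, d)))
    return "right" if handed > 0 else "left"


def build_frame(mesh: TriSurface,
                side_override: Optional[str] = None,
                plane_override: Optional[Plane] = None) -> AnatomicalFrame:
    """Run the estimators and assemble the orthonormal measurement frame."""
    qc: list[str] = []
    plane = plane_override if plane_override is not None else \
        compute_resting_plane(mesh)
    view = _unit(plane.normal)
    shaft_raw = estimate_shaft_axis(mesh, plane)
    shaft = _unit(shaft_raw - np.dot(shaft_raw, view) * view)

    detected = detect_side(mesh, plane, shaft)
    if side_override is not None:
        if side_override not in ("left", "right"):
            raise ValueError("side_override must be 'left' or 'right'")
        if detected != "unknown" and detected != side_override:
            qc.append("side_override_conflicts_heuristic")
        side = side_override
    else:
        side = detected
        if side == "unknown":
            qc.append("side_unknown")

    p1, p2 = _condylar_patches_for(mesh, plane)
    d = _unit(p2.centroid - p1.centroid)
    d = _unit(d - np.dot(d, view) * view - np.dot(d, shaft) * shaft)
    bic = _orient_bicondylar(d, view, shaft,
                             side if side in ("left", "right") else "right")

    # asymmetric posterior condyles can skew the pose (dysplastic condyles)
    if max(p1.count, p2.count) > 2.5 * max(1, min(p1.count, p2.count)):
        qc.append("condylar_contact_asymmetry")

    # the refined plane sits mid-band through the support points, so noisy
    # vertices may dip slightly below it; flag only clear penetration
    if plane.signed_distance(mesh.vertices).min() < -4.0 * CONTACT_TOL_MM:
        qc.append("vertices_below_resting_plane")

    origin = 0.5 * (p1.centroid + p2.centroid)

    # a point on the femoral shaft axis line: centroid of the proximal portion
    verts = mesh.vertices
    coord = verts @ shaft
    hi = coord.max()
    extent = hi - coord.min()
    shaft_line_point = verts[coord >= hi - 0.4 * extent].mean(axis=0)

    return AnatomicalFrame(
        resting_plane=plane,
        shaft_axis=shaft,
        shaft_axis_raw=shaft_raw,
        bicondylar_axis=bic,
        view_axis=view,
        side=side,
        origin=origin,
        shaft_line_point=shaft_line_point,
        condylar_patches=(p1, p2),
        qc_flags=qc,
    )
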