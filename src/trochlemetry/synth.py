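"""Parametric synthetic distal femur with ground-truth clockface annotations.

The phantom is a stylized distal femur built from an implicit solid:

* a shaft capsule running proximally (+y), nearly grazing the resting plane
  so the bone sits stably on three contacts (two condyles + posterior shaft);
* two posterior condylar ellipsoids tangent to the plane ``z = 0`` (the
  medial condyle is larger and shifted distally, which encodes laterality);
* an anterior trochlear block whose top face is an explicit heightfield:
  a flat supratrochlear base carrying two Gaussian ridge bumps offset
  half a groove-width to either side of the groove centerline, minus a
  Gaussian groove dip along the centerline, plus an optional medial-ridge
  amplitude swell emulating a supratrochlear spur.

The groove centerline starts distally near the midline at the clockface
center level and ends proximally at the patellar entry point, placed so the
clockface convention (12 o'clock along the shaft midline, center on the
shaft axis at the groove's distal terminus level) yields exactly
``theta_deg``.  Because each mediolateral profile of the heightfield is
mirror-symmetric about the centerline, the two ridge maxima shift
symmetrically and their midpoint recovers the centerline exactly; the
ground-truth ridge termini are solved numerically from the 1-D profile.

All ground truth is recorded pre-jitter.  The implicit solid is polygonized
with marching cubes at ``mesh_pitch_mm`` and seeded Gaussian vertex jitter
of ``noise_mm`` is applied last.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from skimage.measure import marching_cubes

from .mesh_io import TriSurface

__all__ = ["SynthParams", "GroundTruth", "generate", "make_cohort", "draw_thetas"]

# Internal layout constants (mm), relative to the canonical pose: resting
# plane z=0, shaft along +y, lateral = +lambda before side mapping.
_GROOVE_DISTAL_Y = -10.0   # proximodistal level of the groove's distal terminus
_SHAFT_Y0 = 28.0           # distal end of the shaft capsule axis
_SLAB_Y_LO = -22.0         # distal edge of the trochlear block footprint
_SLAB_Z_LO = 6.0           # posterior face of the trochlear block
_SLAB_ROUND = 4.0          # footprint corner rounding radius
_RIDGE_SIGMA = 3.0         # mediolateral Gaussian width of each ridge bump
_RAMP_MM = 1.5             # ridge/dip amplitude ramp length at trace ends
_SPUR_SIGMA_Y = 3.0        # proximodistal width of the spur swell
_BLEND_K = 1.5             # smooth-union blending scale


@dataclass
class SynthParams:
    """Generator controls.  Lengths in millimetres, angles in degrees."""

    side: str = "left"
    theta_deg: float = 23.0
    obliquity_deg: Optional[float] = None  # None -> straight (radial) course
    spur_height_mm: float = 0.0
    shaft_radius_mm: float = 14.0
    shaft_length_mm: float = 80.0
    condyle_radii_mm: tuple = ((23.0, 26.0, 22.0), (21.0, 23.0, 20.0))
    condyle_separation_mm: float = 46.0
    condyle_distal_shift_mm: float = 3.0
    groove_depth_mm: float = 4.0
    groove_width_mm: float = 16.0
    ridge_height_mm: float = 4.0
    entry_radius_mm: float = 35.0
    base_height_mm: float = 48.0
    shaft_clearance_mm: float = 0.6
    mesh_pitch_mm: float = 1.0
    noise_mm: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        lengths = dict(
            shaft_radius_mm=self.shaft_radius_mm,
            shaft_length_mm=self.shaft_length_mm,
            condyle_separation_mm=self.condyle_separation_mm,
            groove_depth_mm=self.groove_depth_mm,
            groove_width_mm=self.groove_width_mm,
            ridge_height_mm=self.ridge_height_mm,
            entry_radius_mm=self.entry_radius_mm,
            base_height_mm=self.base_height_mm,
            mesh_pitch_mm=self.mesh_pitch_mm,
        )
        for k, v in lengths.items():
            if not v > 0:
                raise ValueError(f"{k} must be > 0, got {v}")
        for triple in self.condyle_radii_mm:
            if len(triple) != 3 or any(r <= 0 for r in triple):
                raise ValueError("condyle_radii_mm must be two positive triples")
        if not (0.0 <= self.theta_deg <= 90.0):
            raise ValueError(f"theta_deg must be in [0, 90], got {self.theta_deg}")
        if self.noise_mm < 0:
            raise ValueError("noise_mm must be >= 0")
        if self.mesh_pitch_mm > self.groove_width_mm / 4.0:
            raise ValueError("mesh_pitch_mm must be <= groove_width_mm / 4")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.obliquity_deg is not None and not (0.0 <= self.obliquity_deg < 90.0):
            raise ValueError("obliquity_deg must be in [0, 90) or None")


@dataclass
class GroundTruth:
    """Pre-jitter analytic truth for every quantity the pipeline recovers."""

    theta_deg: float
    entry_point_xyz: np.ndarray
    clock_center_xyz: np.ndarray
    shaft_axis: np.ndarray          # unit, distal -> proximal
    bicondylar_axis: np.ndarray     # unit, medial -> lateral
    resting_plane_point: np.ndarray
    resting_plane_normal: np.ndarray
    ridge_termini: tuple            # (medial_xyz, lateral_xyz)
    side: str
    vertex_count: int
    obliquity_deg: float            # effective groove-course obliquity
    groove_distal_xyz: np.ndarray
    spur_height_mm: float = 0.0

    def recompute_theta(self) -> float:
        """Clockface angle from stored fields alone (viewing-plane projection)."""
        n = self.resting_plane_normal / np.linalg.norm(self.resting_plane_normal)
        d = self.entry_point_xyz - self.clock_center_xyz
        d = d - np.dot(d, n) * n
        s = self.shaft_axis - np.dot(self.shaft_axis, n) * n
        s = s / np.linalg.norm(s)
        cosang = np.clip(np.dot(d, s) / np.linalg.norm(d), -1.0, 1.0)
        return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# groove centerline
# ---------------------------------------------------------------------------

def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _centerline(theta_deg: float, obliquity_deg: Optional[float],
                R: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Sampled groove centerline (lambda, y) from distal terminus to entry.

    Returns (lam_samples, y_samples, effective_obliquity_deg).  The curve runs
    from D = (0, yD) to E = R*(sin theta, cos theta) + (0, yD); the proximal
    35% is a straight segment at the requested obliquity (default: the radial
    direction, i.e. obliquity == theta).
    """
    yD = _GROOVE_DISTAL_Y
    th = np.radians(theta_deg)
    E = np.array([R * np.sin(th), yD + R * np.cos(th)])
    D = np.array([0.0, yD])
    if obliquity_deg is None or abs(obliquity_deg - theta_deg) < 1e-12:
        t = np.linspace(0.0, 1.0, 257)
        pts = D[None, :] + t[:, None] * (E - D)[None, :]
        return pts[:, 0], pts[:, 1], theta_deg
    phi = np.radians(obliquity_deg)
    u_phi = np.array([np.sin(phi), np.cos(phi)])
    L = np.linalg.norm(E - D)
    J = E - 0.35 * L * u_phi
    if J[1] <= yD + 0.05 * (E[1] - yD):
        raise ValueError(
            "obliquity_deg geometrically infeasible for this theta_deg "
            "(groove course would not be monotonic along the shaft)")
    m = 0.45 * np.linalg.norm(J - D)
    P1 = J - m * u_phi
    P1[1] = np.clip(P1[1], yD + 0.05 * (J[1] - yD), J[1])
    t = np.linspace(0.0, 1.0, 193)
    bez = ((1 - t)[:, None] ** 2 * D[None, :]
           + 2 * ((1 - t) * t)[:, None] * P1[None, :]
           + (t ** 2)[:, None] * J[None, :])
    seg_t = np.linspace(0.0, 1.0, 65)[1:]
    seg = J[None, :] + seg_t[:, None] * (E - J)[None, :]
    pts = np.vstack([bez, seg])
    y = pts[:, 1]
    if np.any(np.diff(y) <= 0):
        raise ValueError(
            "obliquity_deg geometrically infeasible for this theta_deg "
            "(groove course would not be monotonic along the shaft)")
    return pts[:, 0], pts[:, 1], float(obliquity_deg)


# ---------------------------------------------------------------------------
# 1-D ridge/groove profile (per mediolateral slice, centered on the groove)
# ---------------------------------------------------------------------------

def _profile_height(dt: np.ndarray, a_med: float, a_lat: float,
                    depth: float, w: float, sig_g: float) -> np.ndarray:
    """Height added to the flat base at signed offset ``dt`` from the centerline
    (negative = medial)."""
    return (a_med * np.exp(-((dt + w) ** 2) / (2 * _RIDGE_SIGMA ** 2))
            + a_lat * np.exp(-((dt - w) ** 2) / (2 * _RIDGE_SIGMA ** 2))
            - depth * np.exp(-(dt ** 2) / (2 * sig_g ** 2)))


def _ridge_max_offset(a_ridge: float, a_other: float, depth: float,
                      w: float, sig_g: float) -> tuple[float, float]:
    """Locate the lateral-ridge maximum of the 1-D profile numerically.

    Returns (offset_from_centerline, height_above_base).  By mirror symmetry
    the medial maximum for swapped amplitudes sits at the negated offset.
    """
    res = minimize_scalar(
        lambda dt: -_profile_height(np.asarray(dt), a_other, a_ridge, depth, w, sig_g),
        bounds=(w - 2.5, w + 4.0), method="bounded",
        options={"xatol": 1e-10})
    return float(res.x), float(-res.fun)


# ---------------------------------------------------------------------------
# implicit solid
# ---------------------------------------------------------------------------

def _rounded_rect_sdf(x: np.ndarray, y: np.ndarray, hx: float, hy: float,
                      r: float) -> np.ndarray:
    qx = np.abs(x) - hx
    qy = np.abs(y) - hy
    outside = np.hypot(np.maximum(qx, 0.0), np.maximum(qy, 0.0))
    inside = np.minimum(np.maximum(qx, qy), 0.0)
    return outside + inside - r


def _capsule_sdf(p: tuple, a: np.ndarray, b: np.ndarray, r: float) -> np.ndarray:
    px, py, pz = p
    ab = b - a
    ab2 = float(np.dot(ab, ab))
    t = ((px - a[0]) * ab[0] + (py - a[1]) * ab[1] + (pz - a[2]) * ab[2]) / ab2
    t = np.clip(t, 0.0, 1.0)
    dx = px - (a[0] + t * ab[0])
    dy = py - (a[1] + t * ab[1])
    dz = pz - (a[2] + t * ab[2])
    return np.sqrt(dx * dx + dy * dy + dz * dz) - r


def _ellipsoid_sdf(p: tuple, c: np.ndarray, radii: np.ndarray) -> np.ndarray:
    px, py, pz = p
    k = np.sqrt(((px - c[0]) / radii[0]) ** 2
                + ((py - c[1]) / radii[1]) ** 2
                + ((pz - c[2]) / radii[2]) ** 2)
    return (k - 1.0) * float(min(radii))


def _smooth_min(fields: list[np.ndarray], k: float) -> np.ndarray:
    """Log-sum-exp smooth union (numerically stable)."""
    acc = -fields[0] / k
    for f in fields[1:]:
        acc = np.logaddexp(acc, -f / k)
    return -k * acc


def generate(params: SynthParams) -> tuple[TriSurface, GroundTruth]:
    """Build the phantom mesh and its exact pre-jitter ground truth."""
    params.validate()
    p = params
    th = np.radians(p.theta_deg)
    R = p.entry_radius_mm
    yD = _GROOVE_DISTAL_Y
    w = p.groove_width_mm / 2.0
    sig_g = p.groove_width_mm / 4.0
    A = p.ridge_height_mm
    span = R * np.cos(th)
    entry_y = yD + span

    lam_c, y_c, obl_eff = _centerline(p.theta_deg, p.obliquity_deg, R)

    # spur: amplitude swell of the medial ridge near its proximal end
    y_spur = yD + 0.8 * span
    spur_at = lambda y: p.spur_height_mm * np.exp(  # noqa: E731
        -((y - y_spur) ** 2) / (2 * _SPUR_SIGMA_Y ** 2))

    # ridge maxima of the terminal profile -> exact ground-truth termini.
    a_med_end = A + float(spur_at(entry_y))
    off_lat, h_lat = _ridge_max_offset(A, a_med_end, p.groove_depth_mm, w, sig_g)
    off_med_abs, h_med = _ridge_max_offset(a_med_end, A, p.groove_depth_mm, w, sig_g)
    # midpoint correction: with a spur the medial/lateral maxima shift
    # asymmetrically; shift the centerline so the midpoint lands on the ray.
    delta_mid = (off_lat - off_med_abs) / 2.0
    lam_c = lam_c - delta_mid
    entry_lam = R * np.sin(th)

    # grid
    hw = p.condyle_separation_mm / 2.0 + max(
        p.condyle_radii_mm[0][0], p.condyle_radii_mm[1][0])
    slab_y_hi = yD + R + 11.0
    shaft_z = p.shaft_radius_mm + p.shaft_clearance_mm
    y_top = _SHAFT_Y0 + p.shaft_length_mm
    pitch = p.mesh_pitch_mm
    gx = np.arange(-(hw + 4.0), hw + 4.0 + pitch, pitch)
    gy = np.arange(_SLAB_Y_LO - p.condyle_radii_mm[0][1] - 4.0,
                   y_top + p.shaft_radius_mm + 4.0 + pitch, pitch)
    # offset the z grid so flat faces never coincide exactly with grid planes
    # (exact zero crossings at nodes yield degenerate marching-cubes output)
    gz = np.arange(-3.0 + 0.317 * pitch,
                   p.base_height_mm + p.spur_height_mm + 4.0 + pitch, pitch)

    LAM2, Y2 = np.meshgrid(gx, gy, indexing="ij")

    # heightfield of the anterior face (np.interp clamps beyond the course;
    # the amplitude ramp zeroes those regions anyway)
    tc = np.interp(Y2, y_c, lam_c)
    ramp = _smoothstep((Y2 - yD) / _RAMP_MM) * _smoothstep((entry_y - Y2) / _RAMP_MM)
    dt = LAM2 - tc
    a_med = A + p.spur_height_mm * np.exp(-((Y2 - y_spur) ** 2) / (2 * _SPUR_SIGMA_Y ** 2))
    H = p.base_height_mm + ramp * _profile_height(dt, a_med, A, p.groove_depth_mm, w, sig_g)

    # trochlear block footprint
    y_mid = 0.5 * (_SLAB_Y_LO + slab_y_hi)
    rr = _rounded_rect_sdf(LAM2, Y2 - y_mid, hw - _SLAB_ROUND,
                           0.5 * (slab_y_hi - _SLAB_Y_LO) - _SLAB_ROUND, _SLAB_ROUND)

    Z = gz[None, None, :]
    f_block = np.maximum.reduce([
        np.broadcast_to(rr[:, :, None], (len(gx), len(gy), len(gz))),
        _SLAB_Z_LO - Z + np.zeros_like(rr)[:, :, None],
        Z - H[:, :, None],
    ])

    pt = (LAM2[:, :, None], Y2[:, :, None], Z)
    f_shaft = _capsule_sdf(pt, np.array([0.0, _SHAFT_Y0, shaft_z]),
                           np.array([0.0, y_top, shaft_z]), p.shaft_radius_mm)
    sep = p.condyle_separation_mm / 2.0
    rm = np.asarray(p.condyle_radii_mm[0], dtype=float)
    rl = np.asarray(p.condyle_radii_mm[1], dtype=float)
    f_cm = _ellipsoid_sdf(pt, np.array([-sep, -p.condyle_distal_shift_mm, rm[2]]), rm)
    f_cl = _ellipsoid_sdf(pt, np.array([sep, 0.0, rl[2]]), rl)

    f = _smooth_min([f_block, f_shaft, f_cm, f_cl], _BLEND_K)

    verts, faces, _, _ = marching_cubes(f, level=0.0, spacing=(pitch, pitch, pitch))
    verts = verts + np.array([gx[0], gy[0], gz[0]])

    # side mapping: canonical lateral axis is +lambda; left knees keep
    # lateral = +x, right knees are the exact mirror image about x = 0.
    flip = p.side == "right"
    if flip:
        verts[:, 0] = -verts[:, 0]
        faces = faces[:, ::-1]

    import trimesh as _tm
    # round so near-duplicate marching-cubes vertices merge exactly
    mesh = _tm.Trimesh(vertices=np.round(verts, 5), faces=faces, process=True)
    tri = mesh.triangles
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    mesh.update_faces(areas > 1e-12)
    mesh.remove_unreferenced_vertices()
    surf = TriSurface.from_trimesh(
        mesh, name=f"synth_{p.side}_theta{p.theta_deg:g}_seed{p.seed}")

    if p.noise_mm > 0:
        rng = np.random.default_rng(p.seed)
        surf.vertices = surf.vertices + rng.normal(0.0, p.noise_mm, surf.vertices.shape)

    def world(lam: float, y: float, z: float) -> np.ndarray:
        return np.array([-lam if flip else lam, y, z])

    sgn = -1.0 if flip else 1.0
    z_entry = p.base_height_mm + 0.5 * (h_med + h_lat)
    gt = GroundTruth(
        theta_deg=p.theta_deg,
        entry_point_xyz=world(entry_lam, entry_y, z_entry),
        clock_center_xyz=world(0.0, yD, shaft_z),
        shaft_axis=np.array([0.0, 1.0, 0.0]),
        bicondylar_axis=np.array([sgn, 0.0, 0.0]),
        resting_plane_point=np.zeros(3),
        resting_plane_normal=np.array([0.0, 0.0, 1.0]),
        ridge_termini=(
            world(entry_lam - delta_mid - off_med_abs, entry_y, p.base_height_mm + h_med),
            world(entry_lam - delta_mid + off_lat, entry_y, p.base_height_mm + h_lat),
        ),
        side=p.side,
        vertex_count=len(surf.vertices),
        obliquity_deg=obl_eff,
        groove_distal_xyz=world(float(lam_c[0]), yD, p.base_height_mm - p.groove_depth_mm),
        spur_height_mm=p.spur_height_mm,
    )
    return surf, gt


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def draw_thetas(n: int, theta_mean: float, theta_sd: float, seed: int) -> np.ndarray:
    """Draw entry angles from Normal(mean, sd) truncated to [0, 90] degrees."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if theta_sd < 0:
        raise ValueError("theta_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if theta_sd == 0:
        return np.full(n, float(theta_mean))
    from scipy.stats import truncnorm
    a = (0.0 - theta_mean) / theta_sd
    b = (90.0 - theta_mean) / theta_sd
    return truncnorm.rvs(a, b, loc=theta_mean, scale=theta_sd, size=n,
                         random_state=rng)


def make_cohort(n: int, theta_mean: float, theta_sd: float,
                side_policy: str = "alternate", seed: int = 0,
                base: SynthParams | None = None
                ) -> list[tuple[TriSurface, GroundTruth]]:
    """Generate a seeded cohort of synthetic knees.

    Angles are drawn from a truncated normal; per-knee meshing seeds are
    derived deterministically from ``seed``.
    """
    if side_policy not in ("alternate", "all_left", "all_right"):
        raise ValueError(f"unknown side_policy {side_policy!r}")
    thetas = draw_thetas(n, theta_mean, theta_sd, seed)
    sub = np.random.SeedSequence(seed).spawn(n)
    base = base if base is not None else SynthParams()
    out = []
    for i, theta in enumerate(thetas):
        if side_policy == "alternate":
            side = "left" if i % 2 == 0 else "right"
        else:
            side = side_policy.removeprefix("all_")
        knee_seed = int(sub[i].generate_state(1)[0] % (2 ** 31))
        params = replace(base, theta_deg=float(theta), side=side, seed=knee_seed)
        out.append(generate(params))
    return out
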