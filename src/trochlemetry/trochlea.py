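"""Trochlear ridge and groove extraction and the patellar entry point.

The anterior surface is discretized into mediolateral height profiles on
planes perpendicular to the shaft axis.  In each smoothed profile the
trochlea appears as two local maxima (the medial and lateral trochlear
ridges) flanking an interior local minimum (the groove floor).  Detections
are linked across slices into ridge/groove polylines; the traces end
proximally at the last slice where both ridge maxima persist with at least
the prominence threshold — this operationalizes the "convergence" of the
medial and lateral facets.  The patellar entry point is the midpoint of the
two proximal ridge endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .config import PipelineConfig
from .frame import AnatomicalFrame, GeometryError
from .mesh_io import TriSurface

__all__ = [
    "Profile",
    "RidgeTrace",
    "GrooveCourse",
    "EntryPoint",
    "GrooveDetectionError",
    "slice_anterior_profiles",
    "extract_ridges_and_groove",
    "find_entry_point",
    "groove_obliquity",
    "spur_prominence",
]


class GrooveDetectionError(RuntimeError):
    """No two-ridge/one-groove pattern could be traced on the mesh."""


@dataclass
class Profile:
    """Anterior height h(t) of one slice: t mediolateral, s shaft coordinate."""

    s: float
    t: np.ndarray
    h: np.ndarray  # NaN where the slice has no surface at that t


@dataclass
class RidgeTrace:
    which: str                # "medial" or "lateral"
    points: np.ndarray        # (n, 3) world mm, ordered distal -> proximal
    prominence: np.ndarray    # (n,) anterior height above the groove floor
    t: np.ndarray             # frame mediolateral coordinates
    s: np.ndarray             # frame shaft coordinates
    h: np.ndarray             # frame anterior coordinates

    @property
    def proximal_endpoint(self) -> np.ndarray:
        return self.points[-1]


@dataclass
class GrooveCourse:
    points: np.ndarray        # (n, 3) world mm, per-slice groove minima
    t: np.ndarray
    s: np.ndarray
    h: np.ndarray
    obliquity_deg: float = float("nan")


@dataclass
class EntryPoint:
    point: np.ndarray
    from_ridges: tuple  # (medial proximal endpoint, lateral proximal endpoint)


# ---------------------------------------------------------------------------


def slice_anterior_profiles(mesh: TriSurface, frame: AnatomicalFrame,
                            n_slices: int = 120,
                            config: PipelineConfig | None = None
                            ) -> list[Profile]:
    """Anterior height functions on planes perpendicular to the shaft axis,
    spanning the distal portion of the mesh."""
    cfg = config or PipelineConfig()
    if n_slices < 20:
        raise ValueError("n_slices must be >= 20")
    coords = frame.to_coords(mesh.vertices)
    s_all = coords[:, 1]
    s_lo, s_hi = float(s_all.min()), float(s_all.max())
    extent = s_hi - s_lo
    s_cut = s_lo + cfg.distal_fraction * extent
    # slicing finer than the mesh resolution only duplicates profiles (the
    # same triangle rows are cut repeatedly), so floor the slice spacing at
    # the median edge length
    edges = mesh.vertices[mesh.faces[:, [0, 1, 2]]] \
        - mesh.vertices[mesh.faces[:, [1, 2, 0]]]
    median_edge = float(np.median(np.linalg.norm(edges.reshape(-1, 3), axis=1)))
    span = s_cut - (s_lo + 1e-3 * extent)
    n_eff = min(n_slices, max(20, int(span / max(median_edge, 1e-6))))
    heights = np.linspace(s_lo + 1e-3 * extent, s_cut, n_eff)

    mesh_f = trimesh.Trimesh(vertices=coords, faces=mesh.faces, process=False)
    sections = trimesh.intersections.mesh_multiplane(
        mesh_f, plane_origin=np.zeros(3), plane_normal=np.array([0.0, 1.0, 0.0]),
        heights=heights)
    lines_2d, to_3d = sections[0], sections[1]

    dt = cfg.profile_spacing
    profiles: list[Profile] = []
    for k, segs in enumerate(lines_2d):
        if segs is None or len(segs) == 0:
            continue
        pts2 = segs.reshape(-1, 2)
        pts3 = trimesh.transform_points(
            np.c_[pts2, np.zeros(len(pts2))], to_3d[k]).reshape(-1, 2, 3)
        # frame coordinates: x = t (mediolateral), z = h (anterior)
        t0, h0 = pts3[:, 0, 0], pts3[:, 0, 2]
        t1, h1 = pts3[:, 1, 0], pts3[:, 1, 2]
        tmin = float(min(t0.min(), t1.min()))
        tmax = float(max(t0.max(), t1.max()))
        if tmax - tmin < 2 * dt:
            continue
        grid = np.arange(tmin, tmax + dt, dt)
        h = np.full(len(grid), np.nan)
        for a_t, a_h, b_t, b_h in zip(t0, h0, t1, h1):
            if b_t < a_t:
                a_t, b_t = b_t, a_t
                a_h, b_h = b_h, a_h
            i0 = int(np.ceil((a_t - tmin) / dt))
            i1 = int(np.floor((b_t - tmin) / dt))
            if i1 < i0:
                continue
            ti = grid[i0:i1 + 1]
            if b_t - a_t < 1e-12:
                hi = np.full(len(ti), max(a_h, b_h))
            else:
                hi = a_h + (ti - a_t) * (b_h - a_h) / (b_t - a_t)
            cur = h[i0:i1 + 1]
            h[i0:i1 + 1] = np.where(np.isnan(cur), hi, np.maximum(cur, hi))
        if np.count_nonzero(~np.isnan(h)) >= 5:
            profiles.append(Profile(s=float(heights[k]), t=grid, h=h))

    if len(profiles) < 10:
        raise GeometryError(
            f"only {len(profiles)} non-empty anterior profiles; mesh too "
            "small or frame invalid")
    return profiles


# ---------------------------------------------------------------------------


@dataclass
class _Triple:
    s: float
    t_groove: float
    h_groove: float
    t_med: float
    h_med: float
    t_lat: float
    h_lat: float


def _detect_triples(profile: Profile, cfg: PipelineConfig) -> list[_Triple]:
    """All (ridge, groove, ridge) candidates in one smoothed profile."""
    out: list[_Triple] = []
    valid = ~np.isnan(profile.h)
    dt = profile.t[1] - profile.t[0] if len(profile.t) > 1 else cfg.profile_spacing
    sigma = max(cfg.smooth_sigma_mm / dt, 1e-6)
    # contiguous valid runs
    idx = np.nonzero(valid)[0]
    if len(idx) == 0:
        return out
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, len(idx) - 1]
    for a, b in zip(idx[starts], idx[ends]):
        if b - a + 1 < 7:
            continue
        seg_t = profile.t[a:b + 1]
        seg_h = gaussian_filter1d(profile.h[a:b + 1], sigma, mode="nearest")
        peaks, _ = find_peaks(seg_h, prominence=cfg.min_prominence_mm)
        for i in range(len(peaks) - 1):
            p0, p1 = peaks[i], peaks[i + 1]
            inner = seg_h[p0:p1 + 1]
            m = int(np.argmin(inner)) + p0
            if m == p0 or m == p1:
                continue
            if (seg_h[p0] - seg_h[m] < cfg.min_prominence_mm
                    or seg_h[p1] - seg_h[m] < cfg.min_prominence_mm):
                continue
            out.append(_Triple(
                s=profile.s,
                t_groove=float(seg_t[m]), h_groove=float(seg_h[m]),
                t_med=float(seg_t[p0]), h_med=float(seg_h[p0]),
                t_lat=float(seg_t[p1]), h_lat=float(seg_h[p1]),
            ))
    return out


def extract_ridges_and_groove(profiles: list[Profile], frame: AnatomicalFrame,
                              config: PipelineConfig | None = None
                              ) -> tuple[RidgeTrace, RidgeTrace, GrooveCourse]:
    """Trace the two trochlear ridges and the groove across slices.

    Detections are linked distal to proximal by nearest-neighbour groove
    position (gated); the longest chain wins.  Trace termination (both
    maxima losing the prominence threshold) defines facet convergence.
    """
    cfg = config or PipelineConfig()
    profiles = sorted(profiles, key=lambda p: p.s)

    chains: list[list[_Triple]] = []
    open_chains: list[tuple[list[_Triple], int]] = []  # (chain, missed count)
    any_triple = False
    for prof in profiles:
        triples = _detect_triples(prof, cfg)
        any_triple = any_triple or bool(triples)
        matched = set()
        next_open: list[tuple[list[_Triple], int]] = []
        # greedy nearest-neighbour matching with constant-velocity prediction:
        # each chain extrapolates its last step linearly in s, and the gate
        # applies to the residual of all three triple positions, so steep
        # (high-angle) courses track while a chain cannot absorb a detection
        # whose ridge peaks jump even when its groove position lines up
        pairs = []
        for ci, (chain, missed) in enumerate(open_chains):
            prev = chain[-1]
            pred = {"t_groove": prev.t_groove, "t_med": prev.t_med,
                    "t_lat": prev.t_lat}
            # a single-point chain has no slope estimate yet, so its gate is
            # widened to let steep (high-angle) courses bootstrap
            gate = 1.5 * cfg.link_gate_mm
            if len(chain) >= 2:
                gate = cfg.link_gate_mm
                ds = prev.s - chain[-2].s
                if ds > 1e-9:
                    step = 0.0
                    for k in pred:
                        slope = (getattr(prev, k) - getattr(chain[-2], k)) / ds
                        adv = slope * (prof.s - prev.s)
                        pred[k] += adv
                        step = max(step, abs(adv))
                    # peak localization error grows with course steepness
                    # (slice-position uncertainty maps into t as slope * ds)
                    gate += 0.5 * step
            for ti, tr in enumerate(triples):
                d = max(abs(tr.t_groove - pred["t_groove"]),
                        abs(tr.t_med - pred["t_med"]),
                        abs(tr.t_lat - pred["t_lat"]))
                if d <= gate:
                    pairs.append((d, ci, ti))
        pairs.sort(key=lambda x: (x[0], x[1], x[2]))
        used_chains = set()
        for d, ci, ti in pairs:
            if ci in used_chains or ti in matched:
                continue
            open_chains[ci][0].append(triples[ti])
            used_chains.add(ci)
            matched.add(ti)
        for ci, (chain, missed) in enumerate(open_chains):
            if ci in used_chains:
                next_open.append((chain, 0))
            elif missed < cfg.max_link_gap:
                next_open.append((chain, missed + 1))
            else:
                chains.append(chain)
        for ti, tr in enumerate(triples):
            if ti not in matched:
                next_open.append(([tr], 0))
        open_chains = next_open
    chains.extend(chain for chain, _ in open_chains)

    if not any_triple:
        raise GrooveDetectionError(
            "no trochlear groove detected: no slice shows two ridge maxima "
            "flanking an interior minimum")
    chains.sort(key=lambda c: (len(c),
                               sum(tr.h_med + tr.h_lat - 2 * tr.h_groove
                                   for tr in c)))
    chain = chains[-1]
    # a course is only defined by a trace covering several independent
    # slices over a non-trivial proximodistal span
    span = chain[-1].s - chain[0].s
    if len(chain) < 4 or span < 2.5:
        raise GrooveDetectionError(
            f"trochlear groove trace too short ({len(chain)} slices over "
            f"{span:.1f} mm)")

    def trace(which: str) -> RidgeTrace:
        if which == "medial":
            t = np.array([tr.t_med for tr in chain])
            h = np.array([tr.h_med for tr in chain])
        else:
            t = np.array([tr.t_lat for tr in chain])
            h = np.array([tr.h_lat for tr in chain])
        s = np.array([tr.s for tr in chain])
        prom = h - np.array([tr.h_groove for tr in chain])
        pts = frame.from_coords(np.c_[t, s, h])
        return RidgeTrace(which=which, points=pts, prominence=prom, t=t, s=s, h=h)

    medial = trace("medial")
    lateral = trace("lateral")
    tg = np.array([tr.t_groove for tr in chain])
    sg = np.array([tr.s for tr in chain])
    hg = np.array([tr.h_groove for tr in chain])
    groove = GrooveCourse(points=frame.from_coords(np.c_[tg, sg, hg]),
                          t=tg, s=sg, h=hg)
    groove.obliquity_deg = groove_obliquity(groove, frame)
    return medial, lateral, groove


def find_entry_point(medial: RidgeTrace, lateral: RidgeTrace) -> EntryPoint:
    """Midpoint of the two proximal ridge endpoints."""
    if len(medial.points) == 0 or len(lateral.points) == 0:
        raise GrooveDetectionError("empty ridge trace; cannot place entry point")
    pm = medial.proximal_endpoint
    pl = lateral.proximal_endpoint
    return EntryPoint(point=0.5 * (pm + pl), from_ridges=(pm.copy(), pl.copy()))


def groove_obliquity(course: GrooveCourse, frame: AnatomicalFrame) -> float:
    """Angle (deg) between the proximal-quarter groove chord and the shaft
    axis, both projected into the viewing plane."""
    if len(course.s) < 4:
        raise ValueError("groove course must have >= 4 points")
    # recompute coordinates from world points with the supplied frame, so
    # obliquity is always relative to the anatomical shaft axis even if the
    # course was traced in a rotated (obliquely resliced) frame
    coords = frame.to_coords(course.points)
    t, s = coords[:, 0], coords[:, 1]
    cut = s.max() - 0.25 * (s.max() - s.min())
    sel = np.nonzero(s >= cut)[0]
    if len(sel) < 2:
        sel = np.array([len(s) - 2, len(s) - 1])
    i0, i1 = sel[0], sel[-1]
    dt_ = t[i1] - t[i0]
    ds_ = s[i1] - s[i0]
    return float(np.degrees(np.arctan2(abs(dt_), abs(ds_))))


def spur_prominence(medial: RidgeTrace, course: GrooveCourse | None = None
                    ) -> float:
    """Maximum anterior height of the proximal third of the medial ridge
    above the groove floor at the same slice (supratrochlear spur size)."""
    s = medial.s
    cut = s.max() - (s.max() - s.min()) / 3.0
    prom = medial.prominence[s >= cut]
    return float(prom.max()) if len(prom) else 0.0
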