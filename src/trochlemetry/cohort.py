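"""End-to-end per-knee measurement, batch processing and cohort summaries."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .clockface import (DEFAULT_BINS, GradeBins, angle_to_clock, classify,
                        lateralization_angle, set_clock_center)
from .config import CONVENTION, PipelineConfig
from .frame import build_frame
from .mesh_io import MeasurementRecord, TriSurface, load_mesh
from .trochlea import (extract_ridges_and_groove, find_entry_point,
                       groove_obliquity, slice_anterior_profiles,
                       spur_prominence)

__all__ = [
    "measure_mesh",
    "run_batch",
    "summarize",
    "compare_groups",
    "CohortSummary",
    "BatchError",
]

log = logging.getLogger("trochlemetry")


class BatchError(RuntimeError):
    """Every input in a batch failed."""


def measure_mesh(mesh: TriSurface, side: Optional[str] = None,
                 config: PipelineConfig | None = None,
                 knee_id: Optional[str] = None
                 ) -> tuple[MeasurementRecord, dict]:
    """Run frame -> trochlea -> clockface on one knee.

    Returns the measurement record and an audit dictionary with the frame,
    traces, the facet-convergence point (the groove's proximal terminus,
    reported for QC alongside the midpoint entry definition) and the
    resolved configuration.
    """
    cfg = config or PipelineConfig()
    bins = GradeBins(edges=tuple(cfg.grade_edges)) \
        if tuple(cfg.grade_edges) != DEFAULT_BINS.edges else DEFAULT_BINS

    frame = build_frame(mesh, side_override=side)
    log.info("%s: plane n=%s side=%s", mesh.name,
             np.round(frame.resting_plane.normal, 3), frame.side)
    qc = list(mesh.qc_flags) + list(frame.qc_flags)
    profiles = slice_anterior_profiles(mesh, frame, n_slices=cfg.n_slices,
                                       config=cfg)
    medial, lateral, groove = extract_ridges_and_groove(profiles, frame, cfg)
    # obliquity is defined relative to the anatomical shaft axis
    groove.obliquity_deg = groove_obliquity(groove, frame)
    log.info("%s: trace length %d slices, obliquity %.1f deg", mesh.name,
             len(groove.s), groove.obliquity_deg)
    entry = find_entry_point(medial, lateral)
    frame = set_clock_center(frame, groove)
    cm = lateralization_angle(entry, frame)
    if frame.side in ("left", "right"):
        clock_hour = angle_to_clock(cm.lateralization_deg, frame.side)
    else:
        clock_hour = float("nan")
        qc.append("side_unknown_clock_not_mapped")
    grade = classify(cm.lateralization_deg, bins)
    record = MeasurementRecord(
        knee_id=knee_id or mesh.name or "knee",
        side=frame.side,
        lateralization_deg=cm.lateralization_deg,
        clock_hour=clock_hour,
        grade=grade,
        obliquity_deg=groove.obliquity_deg,
        spur_prominence_mm=spur_prominence(medial, groove),
        qc_flags=qc,
    )
    audit = {
        "frame": frame,
        "profiles": profiles,
        "medial": medial,
        "lateral": lateral,
        "groove": groove,
        "entry": entry,
        "signed_deg": cm.signed_deg,
        "convergence_point": groove.points[-1],
        "config": cfg.to_dict(),
        "convention": CONVENTION,
    }
    return record, audit


def _as_mesh(item, idx: int) -> tuple[TriSurface, Optional[str]]:
    if isinstance(item, (str, Path)):
        return load_mesh(item), Path(item).stem
    if isinstance(item, TriSurface):
        return item, item.name or f"knee_{idx:03d}"
    if isinstance(item, tuple) and isinstance(item[0], TriSurface):
        return item[0], item[0].name or f"knee_{idx:03d}"
    raise TypeError(f"cannot interpret batch input of type {type(item)!r}")


def run_batch(inputs: Sequence, config: PipelineConfig | None = None,
              sides: Optional[Sequence[Optional[str]]] = None
              ) -> list[MeasurementRecord]:
    """Measure a batch of knees; per-knee failures become flagged records."""
    if len(inputs) < 1:
        raise ValueError("run_batch needs at least one input")
    cfg = config or PipelineConfig()
    records: list[MeasurementRecord] = []
    failures: list[str] = []
    for i, item in enumerate(inputs):
        side = sides[i] if sides is not None else None
        try:
            mesh, knee_id = _as_mesh(item, i)
            record, _ = measure_mesh(mesh, side=side, config=cfg, knee_id=knee_id)
        except Exception as exc:  # noqa: BLE001 - isolate per-knee failures
            knee_id = getattr(item, "name", None) or (
                Path(item).stem if isinstance(item, (str, Path)) else f"knee_{i:03d}")
            log.warning("%s failed: %s", knee_id, exc)
            failures.append(f"{knee_id}: {exc}")
            record = MeasurementRecord(
                knee_id=str(knee_id), side="unknown",
                lateralization_deg=float("nan"), clock_hour=float("nan"),
                grade="failed", obliquity_deg=float("nan"),
                spur_prominence_mm=float("nan"),
                qc_flags=[f"failed:{type(exc).__name__}:{exc}"],
            )
        records.append(record)
    if len(failures) == len(inputs):
        raise BatchError("all inputs failed:\n" + "\n".join(failures))
    return records


@dataclass
class CohortSummary:
    """Descriptive statistics of measured lateralization angles."""

    n_knees: int
    mean_deg: float
    sd_deg: float        # n-1 sample standard deviation
    min_deg: float
    max_deg: float
    grade_counts: dict
    n_over_30: int       # knees with lateralization > 30 degrees
    n_failed: int = 0


def _usable(records: Sequence[MeasurementRecord]) -> list[MeasurementRecord]:
    return [r for r in records
            if not math.isnan(r.lateralization_deg)
            and not any(f.startswith("failed") for f in r.qc_flags)]


def summarize(records: Sequence[MeasurementRecord],
              bins: GradeBins = DEFAULT_BINS) -> CohortSummary:
    """Cohort mean/SD/range, grade counts and the >30-degree count.

    Failed knees are excluded from the statistics but counted in
    ``n_failed``; no imputation is performed.
    """
    good = _usable(records)
    if len(good) < 2:
        raise ValueError(
            f"need >= 2 usable records to summarize, got {len(good)}")
    angles = np.array([r.lateralization_deg for r in good])
    counts = {label: 0 for label in bins.labels}
    for r in good:
        counts[classify(r.lateralization_deg, bins)] += 1
    return CohortSummary(
        n_knees=len(good),
        mean_deg=float(angles.mean()),
        sd_deg=float(angles.std(ddof=1)),
        min_deg=float(angles.min()),
        max_deg=float(angles.max()),
        grade_counts=counts,
        n_over_30=int(np.count_nonzero(angles > 30.0)),
        n_failed=len(records) - len(good),
    )


def compare_groups(a: CohortSummary, b: CohortSummary):
    """Side-by-side descriptive comparison of two cohorts (no inferential
    statistics; difference of means only)."""
    import pandas as pd

    labels = list(a.grade_counts.keys())
    rows = {
        "n_knees": (a.n_knees, b.n_knees, b.n_knees - a.n_knees),
        "mean_deg": (a.mean_deg, b.mean_deg, b.mean_deg - a.mean_deg),
        "sd_deg": (a.sd_deg, b.sd_deg, b.sd_deg - a.sd_deg),
        "min_deg": (a.min_deg, b.min_deg, b.min_deg - a.min_deg),
        "max_deg": (a.max_deg, b.max_deg, b.max_deg - a.max_deg),
        "n_over_30": (a.n_over_30, b.n_over_30, b.n_over_30 - a.n_over_30),
    }
    for lab in labels:
        rows[f"grade_{lab}"] = (a.grade_counts.get(lab, 0),
                                b.grade_counts.get(lab, 0),
                                b.grade_counts.get(lab, 0)
                                - a.grade_counts.get(lab, 0))
    return pd.DataFrame(rows, index=["group_a", "group_b", "difference"]).T
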