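"""Per-spine morphometric measurements.

Produces the per-spine record analyzed throughout the pipeline: neck length,
mean/minimum neck cross-sectional area and equivalent diameter, the
along-neck coefficient of variation of the diameter, and head volume.  All
quantities derive from the centerline cross-section profile; the head volume
is the part of the mesh apical of the neck/head boundary plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np

from .centerline import (
    Centerline,
    CrossSectionProfile,
    DegenerateSpineError,
    compute_centerline,
    find_neck_bounds,
    profile_neck_window,
    profile_spine,
    refine_neck_boundaries,
)
from .electrics import ResistivityModel, neck_resistance, \
    neck_resistance_integral
from .meshio import SpineMesh

log = logging.getLogger(__name__)

__all__ = ["SpineMorphometry", "MeasureConfig", "neck_length", "neck_stats",
           "head_volume", "measure_spine"]


@dataclass
class MeasureConfig:
    """Geometry-measurement settings.

    station_spacing : um between cross-sections (the classic ~150 nm).
    boundary_alpha  : neck/head and neck/dendrite boundary threshold as a
                      multiple of the minimum neck diameter.
    min_neck_stations : if the neck spans fewer stations, the spine is
                      re-profiled at a finer spacing (short spines); eight
                      stations keep the unweighted station mean from being
                      dominated by a single flare-shoulder station.
    """

    station_spacing: float = 0.15
    boundary_alpha: float = 1.5
    min_neck_stations: int = 8
    voxel_pitch: float | None = None
    rho_ohm_cm: float = 109.0


@dataclass
class SpineMorphometry:
    """One spine's measured record (units: um, um^2, um^3, percent, MOhm)."""

    spine_id: str
    condition: str = ""
    modality: str = ""
    neck_length: float = np.nan
    neck_area_mean: float = np.nan
    neck_area_min: float = np.nan
    neck_diam_mean: float = np.nan
    neck_diam_min: float = np.nan
    neck_diam_cv: float = np.nan
    head_volume: float = np.nan
    er_in_neck: bool | None = None
    synapse_area: float = np.nan
    resistance_mohm: float = np.nan
    resistance_min_area_mohm: float = np.nan
    resistance_integral_mohm: float = np.nan
    cap_position: float = np.nan        # boundary plane arclength, for audit
    flags: list[str] = field(default_factory=list)
    error: str = ""

    def as_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = ";".join(v) if f.name == "flags" else v
        return out


def neck_length(centerline: Centerline, profile: CrossSectionProfile) -> float:
    """Arc length of the centerline between the refined neck boundaries."""
    if profile.neck_s_end <= profile.neck_s_start:
        raise DegenerateSpineError("invalid neck bounds")
    return float(profile.neck_s_end - profile.neck_s_start)


def neck_stats(profile: CrossSectionProfile) -> dict[str, float]:
    """Unweighted mean/min of neck-station areas and diameters plus the CV.

    The CV is 100 * sample SD / mean of the per-station equivalent
    diameters; with fewer than two neck stations it is NaN and the spine is
    flagged.
    """
    sl = profile.neck_slice
    a = profile.area[sl]
    y = profile.diameter[sl]
    if len(a) == 0:
        raise DegenerateSpineError("no neck stations")
    if len(y) >= 2:
        cv = 100.0 * float(np.std(y, ddof=1) / np.mean(y))
    else:
        cv = np.nan
        profile.flags.append("cv_undefined")
    return {
        "neck_area_mean": float(a.mean()),
        "neck_area_min": float(a.min()),
        "neck_diam_mean": float(y.mean()),
        "neck_diam_min": float(y.min()),
        "neck_diam_cv": cv,
    }


def head_volume(mesh: SpineMesh, centerline: Centerline,
                profile: CrossSectionProfile) -> float:
    """Volume of the mesh apical of the neck/head boundary plane.

    The mesh is cut by the section plane at the refined neck end; the volume
    of the open apical piece is evaluated by signed-tetrahedron summation
    with the reference origin *on* the cut plane, which closes the region
    exactly as the planar cap would.
    """
    import trimesh.intersections as ti

    s_end = profile.neck_s_end
    origin = centerline.point_at(s_end)[0]
    normal = centerline.tangent_at(s_end)[0]     # points toward the head
    piece = ti.slice_mesh_plane(mesh.trimesh, plane_normal=normal,
                                plane_origin=origin, cap=False)
    if len(piece.faces) == 0:
        raise DegenerateSpineError("boundary plane does not cut the mesh")
    tris = (piece.vertices - origin)[piece.faces]
    vol = float(np.einsum("ij,ij->i", tris[:, 0],
                          np.cross(tris[:, 1], tris[:, 2])).sum() / 6.0)
    vol = abs(vol)
    total = abs(mesh.volume)
    if not (0 < vol < total):
        raise DegenerateSpineError(
            f"boundary plane failed to separate head ({vol:.3g} of {total:.3g})")
    return vol


def _profile_with_bounds(mesh: SpineMesh, cl: Centerline, cfg: MeasureConfig,
                         spacing: float) -> CrossSectionProfile:
    prof = profile_spine(mesh, cl, spacing=spacing)
    find_neck_bounds(prof, alpha=cfg.boundary_alpha)
    refine_neck_boundaries(mesh, cl, prof, alpha=cfg.boundary_alpha)
    return prof


def measure_spine(mesh: SpineMesh, config: MeasureConfig | None = None,
                  condition: str = "", modality: str = "") -> SpineMorphometry:
    """Full measurement chain: centerline -> profile -> bounds -> record.

    Never raises for per-spine geometry failures: errors are recorded on the
    returned record (``error`` non-empty) so batch runs continue.
    """
    cfg = config or MeasureConfig()
    rec = SpineMorphometry(spine_id=mesh.spine_id, condition=condition,
                           modality=modality)
    try:
        cl = compute_centerline(mesh, spacing=cfg.station_spacing,
                                pitch=cfg.voxel_pitch)
        prof = _profile_with_bounds(mesh, cl, cfg, cfg.station_spacing)

        # thin necks: re-extract the centerline on a finer voxel grid, but
        # keep the first pass if the finer one misbehaves (fine grids thin
        # wide stubs/heads into noisy medial sheets)
        d_min = float(prof.diameter[prof.neck_slice].min())
        if cfg.voxel_pitch is None and d_min < 6 * 0.015:
            pitch2 = float(np.clip(d_min / 6.0, 0.005, 0.015))
            # keep the refined grid below ~4M voxels
            extent = np.ptp(mesh.vertices, axis=0) + 4 * pitch2
            pitch_mem = float((np.prod(extent) / 4e6) ** (1.0 / 3.0))
            pitch2 = max(pitch2, pitch_mem)
            if pitch2 < 0.014:
                cl2 = compute_centerline(mesh, spacing=cfg.station_spacing,
                                         pitch=pitch2)
                prof2 = _profile_with_bounds(mesh, cl2, cfg,
                                             cfg.station_spacing)
                bad = {"centerline_excursion", "kinked"}
                if not (bad & set(prof2.flags)) or (bad & set(prof.flags)):
                    cl, prof = cl2, prof2

        # short necks: re-profile at a finer spacing so the boundary search
        # has a usable station count
        n_neck = prof.neck_end_index - prof.neck_start_index + 1
        if n_neck < cfg.min_neck_stations:
            span = max(prof.neck_s_end - prof.neck_s_start,
                       2 * prof.s.min(), 0.05)
            spacing2 = min(cfg.station_spacing, span / cfg.min_neck_stations)
            prof = _profile_with_bounds(mesh, cl, cfg, spacing2)
            prof.flags.append("fine_spacing")

        rec.flags = sorted(set(prof.flags))
        rec.neck_length = neck_length(cl, prof)
        # neck statistics on a midpoint partition of the refined window so
        # the unweighted station mean estimates the along-neck mean
        span = prof.neck_s_end - prof.neck_s_start
        n_sta = max(cfg.min_neck_stations,
                    int(round(span / cfg.station_spacing)))
        window = profile_neck_window(mesh, cl, prof.neck_s_start,
                                     prof.neck_s_end, n_sta)
        for k, v in neck_stats(window).items():
            setattr(rec, k, v)
        rec.cap_position = prof.neck_s_end
        rec.head_volume = head_volume(mesh, cl, prof)
        model = ResistivityModel(cfg.rho_ohm_cm)
        rec.resistance_mohm = neck_resistance(rec.neck_length,
                                              rec.neck_area_mean, model)
        rec.resistance_min_area_mohm = neck_resistance(rec.neck_length,
                                                       rec.neck_area_min,
                                                       model)
        rec.resistance_integral_mohm = neck_resistance_integral(window, model)
    except (DegenerateSpineError, Exception) as exc:  # noqa: BLE001
        rec.error = f"{type(exc).__name__}: {exc}"
        log.warning("spine %s failed: %s", mesh.spine_id, rec.error)
    return rec
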