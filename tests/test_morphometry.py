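"""Per-spine morphometry: length, stats, head volume, full recovery."""

import numpy as np
import pytest

from helpers import build_spine_mesh
from spinemorph.centerline import (CrossSectionProfile, compute_centerline,
                                   find_neck_bounds, profile_spine,
                                   refine_neck_boundaries)
from spinemorph.morphometry import (MeasureConfig, head_volume, measure_spine,
                                    neck_length, neck_stats)
from spinemorph.synthetic import cryo_default_spec, make_spine_mesh, \
    sample_population


def make_profile(s, diam, s_start=None, s_end=None):
    diam = np.asarray(diam, dtype=float)
    prof = CrossSectionProfile(
        s=np.asarray(s, dtype=float), area=np.pi * diam**2 / 4.0,
        diameter=diam, polygons=[None] * len(diam),
        neck_start_index=0, neck_end_index=len(diam) - 1,
        neck_s_start=s_start if s_start is not None else float(s[0]),
        neck_s_end=s_end if s_end is not None else float(s[-1]))
    return prof


class TestNeckLength:
    def test_constructed_one_micron_neck(self, straight_spine):
        solid, mesh = straight_spine
        cl = compute_centerline(mesh)
        prof = profile_spine(mesh, cl)
        find_neck_bounds(prof)
        refine_neck_boundaries(mesh, cl, prof)
        lo, hi = solid.threshold_crossings(1.5 * 0.2)
        assert neck_length(cl, prof) == pytest.approx(hi - lo, rel=0.02)

    def test_bent_neck_reports_path_length_not_chord(self, bent_spine):
        solid, mesh = bent_spine
        cl = compute_centerline(mesh)
        prof = profile_spine(mesh, cl)
        find_neck_bounds(prof)
        refine_neck_boundaries(mesh, cl, prof)
        arc = neck_length(cl, prof)
        chord = np.linalg.norm(cl.point_at(prof.neck_s_end)[0]
                               - cl.point_at(prof.neck_s_start)[0])
        lo, hi = solid.threshold_crossings(1.5 * 0.2)
        assert arc == pytest.approx(hi - lo, rel=0.02)  # path length
        assert arc > chord * 1.001                      # not the chord


class TestNeckStats:
    def test_constant_neck(self):
        prof = make_profile([0.0, 0.15, 0.3], [0.2, 0.2, 0.2])
        st = neck_stats(prof)
        assert st["neck_diam_mean"] == pytest.approx(0.2)
        assert st["neck_diam_min"] == pytest.approx(0.2)
        assert st["neck_diam_cv"] == pytest.approx(0.0, abs=1e-9)

    def test_two_station_hand_computation(self):
        # Y = {0.1, 0.2}: mean 0.15, min 0.1, sample SD 0.07071 -> CV 47.14%
        prof = make_profile([0.0, 0.15], [0.1, 0.2])
        st = neck_stats(prof)
        assert st["neck_diam_mean"] == pytest.approx(0.15)
        assert st["neck_diam_min"] == pytest.approx(0.1)
        assert st["neck_diam_cv"] == pytest.approx(
            100 * np.std([0.1, 0.2], ddof=1) / 0.15, rel=1e-9)
        assert st["neck_diam_cv"] == pytest.approx(47.14, abs=0.01)

    def test_single_station_cv_flagged(self):
        prof = make_profile([0.0], [0.2])
        st = neck_stats(prof)
        assert np.isnan(st["neck_diam_cv"])
        assert "cv_undefined" in prof.flags


class TestHeadVolume:
    def test_sphere_head_within_3_percent(self, straight_spine):
        solid, mesh = straight_spine
        cl = compute_centerline(mesh)
        prof = profile_spine(mesh, cl)
        find_neck_bounds(prof)
        refine_neck_boundaries(mesh, cl, prof)
        lo, hi = solid.threshold_crossings(1.5 * 0.2)
        gt = solid.volume_between(hi, solid.t_apex)
        assert head_volume(mesh, cl, prof) == pytest.approx(gt, rel=0.03)

    def test_volume_conservation(self, straight_spine):
        # head + basal remainder = whole mesh volume
        import trimesh.intersections as ti
        solid, mesh = straight_spine
        cl = compute_centerline(mesh)
        prof = profile_spine(mesh, cl)
        find_neck_bounds(prof)
        refine_neck_boundaries(mesh, cl, prof)
        vh = head_volume(mesh, cl, prof)
        origin = cl.point_at(prof.neck_s_end)[0]
        normal = -cl.tangent_at(prof.neck_s_end)[0]
        piece = ti.slice_mesh_plane(mesh.trimesh, plane_normal=normal,
                                    plane_origin=origin, cap=False)
        tris = (piece.vertices - origin)[piece.faces]
        v_rest = abs(np.einsum("ij,ij->i", tris[:, 0],
                               np.cross(tris[:, 1], tris[:, 2])).sum() / 6)
        assert vh + v_rest == pytest.approx(mesh.volume, rel=1e-6)

    def test_voxel_counting_oracle(self, straight_spine):
        # independent voxel-count of the apical region agrees within a
        # surface-layer tolerance
        from spinemorph.voxel import voxelize_binary
        solid, mesh = straight_spine
        cl = compute_centerline(mesh)
        prof = profile_spine(mesh, cl)
        find_neck_bounds(prof)
        refine_neck_boundaries(mesh, cl, prof)
        vh = head_volume(mesh, cl, prof)
        pitch = 0.008
        grid = voxelize_binary(mesh.trimesh, pitch)
        idx = np.argwhere(grid.occupancy)
        pts = grid.index_to_world(idx)
        origin = cl.point_at(prof.neck_s_end)[0]
        normal = cl.tangent_at(prof.neck_s_end)[0]
        apical = ((pts - origin) @ normal) > 0
        v_vox = apical.sum() * pitch**3
        area_scale = (vh / 0.008) * 2  # rough apical surface area bound
        assert abs(v_vox - vh) < max(0.02 * vh, area_scale * pitch * 0.5)


class TestMeasureSpine:
    def test_noise_free_recovery_within_5_percent(self):
        import dataclasses
        spec = dataclasses.replace(cryo_default_spec(n_spines=4, seed=17),
                                   within_spine_cv=0.0, within_spine_cv_sd=0.0)
        for gt in sample_population(spec):
            rec = measure_spine(make_spine_mesh(gt))
            assert rec.error == ""
            assert rec.neck_diam_mean == pytest.approx(gt.neck_mean_diameter,
                                                       rel=0.05)
            assert rec.neck_length == pytest.approx(gt.neck_length, rel=0.05)
            assert rec.head_volume == pytest.approx(gt.head_volume, rel=0.05)

    def test_scaling_covariance(self, straight_spine):
        from spinemorph.meshio import SpineMesh
        _, mesh = straight_spine
        rec = measure_spine(mesh)
        k = 1.6
        scaled = SpineMesh(mesh.vertices * k, mesh.faces.copy(),
                           mesh.base_point * k, "scaled").validate()
        rec_k = measure_spine(scaled)
        assert rec_k.neck_length == pytest.approx(k * rec.neck_length,
                                                  rel=0.01)
        assert rec_k.neck_area_mean == pytest.approx(k**2 * rec.neck_area_mean,
                                                     rel=0.01)
        assert rec_k.head_volume == pytest.approx(k**3 * rec.head_volume,
                                                  rel=0.01)

    def test_batch_has_no_hard_failures(self, small_cryo_population):
        for gt in small_cryo_population:
            rec = measure_spine(make_spine_mesh(gt))
            assert rec.error == ""
            assert rec.neck_area_min <= rec.neck_area_mean

    def test_degraded_recovery_within_10_percent(self):
        from spinemorph.meshio import sectioned_degrade
        solid, mesh = build_spine_mesh(d0=0.128, length=1.0, rh=0.25,
                                       bend_deg=30.0, resolution=0.008)
        lo, hi = solid.threshold_crossings(1.5 * 0.128)
        rec = measure_spine(sectioned_degrade(mesh, 0.05, 0.01))
        assert rec.error == ""
        t = np.linspace(lo, hi, 1001)
        gt_diam = solid.diameter(t).mean()
        assert rec.neck_diam_mean == pytest.approx(gt_diam, rel=0.10)
        assert rec.neck_length == pytest.approx(hi - lo, rel=0.10)
        assert rec.head_volume == pytest.approx(
            solid.volume_between(hi, solid.t_apex), rel=0.10)

    def test_malformed_mesh_recorded_not_raised(self):
        from spinemorph.meshio import SpineMesh
        tiny = SpineMesh(np.array([[0, 0, 0.0], [1e-4, 0, 0], [0, 1e-4, 0],
                                   [0, 0, 1e-4]]),
                         np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3],
                                   [1, 3, 2]]),
                         np.zeros(3), "degenerate")
        rec = measure_spine(tiny, MeasureConfig())
        assert rec.error != ""
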