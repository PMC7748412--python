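"""Validation benchmarks: ground-truth recovery, analytic oracles,
statistical-engine calibration, and the full simulated study.

These routines power both the package's acceptance-style tests and the
stand-alone reproduction script; every quantity is recomputed from scratch
through the public pipeline.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .centerline import compute_centerline, find_neck_bounds, plane_section, \
    profile_spine
from .electrics import ResistivityModel, neck_resistance, \
    neck_resistance_integral, voltage_drop
from .geometry import SpineSolid, sweep_mesh
from .meshio import SpineMesh, sectioned_degrade
from .morphometry import measure_spine
from .stats import spearman, tukey_er_comparison
from .synthetic import PopulationSpec, chemical_default_spec, \
    cryo_default_spec, lognormal_from_moments, make_spine_mesh, \
    sample_population

__all__ = ["recovery_panel", "analytic_oracles", "resistance_checks",
           "statistical_calibration", "spearman_exactness"]


# ------------------------------------------------------------- recovery panel
def _quantile_panel_spec(base: PopulationSpec, n: int, seed: int,
                         q_lo: float = 0.15, q_hi: float = 0.85
                         ) -> list[dict]:
    """Noise-free parameter combinations spanning the condition's printed
    distributions: Latin-hypercube pairing of per-parameter log-normal
    quantiles between ``q_lo`` and ``q_hi``."""
    rng = np.random.default_rng(seed)
    levels = np.linspace(q_lo, q_hi, n)
    cols = {}
    for name, (mean, sd) in {
        "d": (base.neck_diam_mean, base.neck_diam_sd),
        "L": (base.neck_len_mean, base.neck_len_sd),
        "V": (base.head_vol_mean, base.head_vol_sd),
    }.items():
        mu, sig = lognormal_from_moments(mean, sd)
        vals = np.exp(mu + sig * sps.norm.ppf(levels))
        cols[name] = rng.permutation(vals)
    return [{"d": cols["d"][i], "L": cols["L"][i], "V": cols["V"][i]}
            for i in range(n)]


def recovery_panel(seed: int, n: int = 50, degraded: bool = True,
                   section_thickness: float = 0.05, pixel_size: float = 0.01
                   ) -> dict[str, float]:
    """Measure noise-free spines spanning the printed parameter ranges.

    Returns the maximum per-spine relative error (percent) of neck mean
    diameter, neck length and head volume against the constructive ground
    truth, for the clean meshes and (optionally) after 50 nm serial-section
    degradation.
    """
    panel = _quantile_panel_spec(cryo_default_spec(), n - n // 2, seed)
    panel += _quantile_panel_spec(chemical_default_spec(), n // 2, seed + 1)

    errs_clean = {"neck_diam": [], "neck_length": [], "head_volume": []}
    errs_deg = {"neck_diam": [], "neck_length": [], "head_volume": []}
    for i, p in enumerate(panel):
        d0, length = p["d"], p["L"]
        rh = max((3.0 * p["V"] / (4.0 * np.pi)) ** (1 / 3), 0.975 * d0)

        def radius(u, _r=d0 / 2.0):
            return np.full_like(np.asarray(u, dtype=float), _r)

        def build(lc):
            return SpineSolid(max(0.25, 0.99 * d0), max(0.22, 0.9 * d0),
                              0.04, lc, radius, rh, np.deg2rad(30.0))

        # calibrate the core so the operational neck length equals `length`
        thr = 1.5 * d0
        f1 = np.subtract(*build(1.0).threshold_crossings(thr)[::-1])
        f2 = np.subtract(*build(2.0).threshold_crossings(thr)[::-1])
        g = f2 - f1
        solid = build(max((length - (f1 - g)) / g, 0.05))
        lo, hi = solid.threshold_crossings(thr)
        gt_len = hi - lo
        gt_vol = solid.volume_between(hi, solid.t_apex)
        # operational mean diameter: the boundary-to-boundary window also
        # contains the sub-threshold flare shoulders
        t_neck = np.linspace(lo, hi, 1501)
        gt_diam = float(solid.diameter(t_neck).mean())

        v, f = sweep_mesh(solid, min(0.008, d0 / 5.0))
        mesh = SpineMesh(v, f, solid.axis.point(0.0)[0], f"panel_{i:02d}")
        mesh.validate()

        for errs, m in ((errs_clean, mesh),
                        (errs_deg, sectioned_degrade(
                            mesh, section_thickness, pixel_size)
                         if degraded else None)):
            if m is None:
                continue
            rec = measure_spine(m)
            if rec.error:
                errs["neck_diam"].append(np.inf)
                continue
            errs["neck_diam"].append(abs(rec.neck_diam_mean / gt_diam - 1))
            errs["neck_length"].append(abs(rec.neck_length / gt_len - 1))
            errs["head_volume"].append(abs(rec.head_volume / gt_vol - 1))

    out = {f"clean_{k}_maxerr_pct": 100.0 * max(v)
           for k, v in errs_clean.items()}
    if degraded:
        out.update({f"degraded_{k}_maxerr_pct": 100.0 * max(v)
                    for k, v in errs_deg.items()})
    out["n_spines"] = len(panel)
    return out


# ------------------------------------------------------------ analytic oracles
def analytic_oracles() -> dict[str, float]:
    """Cross-section and volume computations against closed forms (percent
    errors): perpendicular cylinder cut, 45-degree elliptical cut, sphere
    volume, and capped-sphere head volume."""
    import trimesh

    out = {}
    r = 0.1
    cyl = trimesh.creation.cylinder(radius=r, height=2.0, sections=256)
    a_perp, _ = plane_section(cyl, np.zeros(3), np.array([0.0, 0.0, 1.0]))
    out["cylinder_section_err_pct"] = 100 * abs(a_perp / (np.pi * r**2) - 1)

    n45 = np.array([0.0, 1.0, 1.0]) / np.sqrt(2)
    a_45, _ = plane_section(cyl, np.zeros(3), n45)
    ellipse = np.pi * r * (r / np.cos(np.pi / 4))
    out["oblique_ellipse_err_pct"] = 100 * abs(a_45 / ellipse - 1)

    sph = trimesh.creation.icosphere(subdivisions=5, radius=0.3)
    out["sphere_volume_err_pct"] = 100 * abs(
        sph.volume / ((4 / 3) * np.pi * 0.3**3) - 1)
    a_eq, _ = plane_section(sph, np.zeros(3), np.array([0.0, 0.0, 1.0]))
    out["sphere_great_circle_err_pct"] = 100 * abs(
        a_eq / (np.pi * 0.3**2) - 1)

    # capped-sphere head volume measured through the full pipeline
    def radius(u):
        return np.full_like(np.asarray(u, dtype=float), 0.1)
    solid = SpineSolid(0.25, 0.22, 0.04, 1.0, radius, 0.3, 0.0)
    v, f = sweep_mesh(solid, 0.008)
    mesh = SpineMesh(v, f, solid.axis.point(0.0)[0], "cap_oracle").validate()
    rec = measure_spine(mesh)
    lo, hi = solid.threshold_crossings(1.5 * 0.2)
    gt = solid.volume_between(hi, solid.t_apex)
    out["capped_head_volume_err_pct"] = 100 * abs(rec.head_volume / gt - 1)
    return out


# ---------------------------------------------------------------- resistances
def resistance_checks(seed: int = 0) -> dict[str, float]:
    """Ohm's-law arithmetic and the series-integral inequality."""
    out = {
        "resistance_1um_1um2_mohm": neck_resistance(1.0, 1.0),
        "resistance_printed_means_mohm": neck_resistance(0.770, 0.0159),
        "voltage_1gohm_1pa_mv": voltage_drop(1e9, 1e-12) * 1e3,
        "voltage_110mohm_20pa_mv": voltage_drop(110e6, 20e-12) * 1e3,
    }
    # series-integral >= mean-area formula on every profiled spine
    spines = sample_population(cryo_default_spec(n_spines=8, seed=seed))
    model = ResistivityModel()
    ratios = []
    for gt in spines:
        mesh = make_spine_mesh(gt)
        cl = compute_centerline(mesh)
        prof = profile_spine(mesh, cl)
        find_neck_bounds(prof)
        sl = prof.neck_slice
        if prof.neck_end_index - prof.neck_start_index < 1:
            continue
        length = float(prof.s[sl][-1] - prof.s[sl][0])
        prof.neck_s_start, prof.neck_s_end = float(prof.s[sl][0]), \
            float(prof.s[sl][-1])
        r_int = neck_resistance_integral(prof, model)
        r_mean = neck_resistance(length, float(prof.area[sl].mean()), model)
        ratios.append(r_int / r_mean)
    out["integral_over_mean_ratio_min"] = float(min(ratios))
    return out


# ---------------------------------------------------------------- calibration
def statistical_calibration(seed: int, n_reps_ks: int = 2000,
                            n_reps_tukey: int = 800) -> dict[str, float]:
    """Type-I error of the K-S and Tukey batteries under null simulations."""
    rng = np.random.default_rng(seed)
    mu, sig = lognormal_from_moments(0.128, 0.0628)
    rej = 0
    for _ in range(n_reps_ks):
        x = np.exp(rng.normal(mu, sig, 100))
        y = np.exp(rng.normal(mu, sig, 100))
        rej += sps.ks_2samp(x, y, method="asymp").pvalue < 0.05
    out = {"ks_null_rejection_rate": rej / n_reps_ks}

    fwe = 0
    for _ in range(n_reps_tukey):
        groups = [rng.normal(0, 1, 25) for _ in range(4)]
        res = sps.tukey_hsd(*groups)
        pmin = min(res.pvalue[i, j]
                   for i, j in itertools.combinations(range(4), 2))
        fwe += pmin < 0.05
    out["tukey_familywise_error_rate"] = fwe / n_reps_tukey
    return out


def spearman_exactness(seed: int, n_samples: int = 20) -> float:
    """Max |p - exhaustive permutation oracle p| over small paired samples."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_samples):
        n = int(rng.integers(4, 8))
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        res = spearman(x, y)
        # independent oracle: enumerate all rank permutations and count
        # correlations at least as extreme
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(sps.pearsonr(rx, ry).statistic)
        hits = total = 0
        for perm in itertools.permutations(ry):
            r = sps.pearsonr(rx, np.asarray(perm)).statistic
            hits += abs(r) >= obs - 1e-12
            total += 1
        worst = max(worst, abs(res.p - hits / total))
    return worst


# --------------------------------------------------------- ER-group benchmark
def er_group_pattern(seed: int) -> dict[str, float]:
    """Tukey contrasts on a default-size two-condition population: head
    volume should separate +/-ER within each condition, neck length should
    not."""
    import pandas as pd

    frames = []
    for spec in (cryo_default_spec(116, seed=seed),
                 chemical_default_spec(150, seed=seed + 1)):
        spines = sample_population(spec)
        frames.append(pd.DataFrame(
            {"condition": [s.condition for s in spines],
             "er_in_neck": [s.er_in_neck for s in spines],
             "neck_length": [s.neck_length for s in spines],
             "head_volume": [s.head_volume for s in spines]}))
    df = pd.concat(frames, ignore_index=True)
    out = {}
    for resp in ("head_volume", "neck_length"):
        t = tukey_er_comparison(df, resp)
        within = t[t.within_condition]
        for _, row in within.iterrows():
            cond = row.group_a[:-3]
            out[f"tukey_{resp}_{cond}_p"] = row.p_adj
    return out
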