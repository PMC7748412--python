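"""End-to-end runs: simulated study, mesh-batch measurement, table re-analysis.

``run_simulated_study`` generates both condition populations, meshes and
measures every spine, computes neck resistances, and runs the full
statistical battery, writing one CSV per analysis plus a
plain-text summary.  ``run_measure`` applies the measurement chain to user
meshes; ``run_reanalyze`` recomputes every statistic from a per-spine
morphometry table alone (no meshes), so that
simulate = generate + measure + reanalyze composed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .electrics import ResistivityModel, neck_resistance, neck_resistance_integral
from .meshio import SpineMesh, read_base_points, read_mesh, sectioned_degrade, \
    write_base_points, write_mesh
from .morphometry import MeasureConfig, measure_spine
from .stats import fit_lognormal, ks_two_sample, linear_r2, spearman, \
    summarize_condition, tukey_er_comparison
from .synthetic import chemical_default_spec, cryo_default_spec, \
    ground_truth_frame, make_spine_mesh, sample_population

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_simulated_study", "run_measure", "run_reanalyze"]

#: the six distribution measurands compared between conditions
MEASURANDS = ["neck_area_mean", "neck_area_min", "neck_diam_mean",
              "neck_diam_min", "neck_length", "head_volume"]


@dataclass
class RunConfig:
    """Settings for one pipeline run."""

    mode: str = "simulate"            # simulate | measure | reanalyze
    n_cryo: int = 116
    n_chem: int = 150
    seed: int = 0
    out_dir: str | Path = "spinemorph_out"
    station_spacing: float = 0.15     # um
    boundary_alpha: float = 1.5
    resolution: float | None = None   # mesh axial step (um); None = auto
    rho_ohm_cm: float = 109.0
    sectioned: bool = False           # degrade meshes before measuring
    section_thickness: float = 0.05   # um
    pixel_size: float = 0.01          # um
    mesh_format: str = "obj"
    save_meshes: bool = False
    log_transform_tukey: bool = False
    synapse_n: int = 33               # cryo subsample for the synapse fit
    max_failure_fraction: float = 0.05
    column_map: dict[str, str] = field(default_factory=dict)
    # per-condition PopulationSpec field overrides, e.g.
    # {"cryo": {"within_spine_cv": 0.0}, "chemical": {"neck_head_rho": 0.2}}
    population_overrides: dict[str, dict] = field(default_factory=dict)

    def measure_config(self) -> MeasureConfig:
        return MeasureConfig(station_spacing=self.station_spacing,
                             boundary_alpha=self.boundary_alpha,
                             rho_ohm_cm=self.rho_ohm_cm)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic sub-seeds below 2^31 derived from one root seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.9g")


def _add_resistances(df: pd.DataFrame, model: ResistivityModel) -> pd.DataFrame:
    df = df.copy()
    r_mean, r_min = [], []
    for _, row in df.iterrows():
        ok = row.get("neck_length", np.nan) > 0 and \
            row.get("neck_area_mean", np.nan) > 0
        r_mean.append(neck_resistance(row["neck_length"], row["neck_area_mean"],
                                      model) if ok else np.nan)
        r_min.append(neck_resistance(row["neck_length"], row["neck_area_min"],
                                     model)
                     if ok and row.get("neck_area_min", 0) > 0 else np.nan)
    df["resistance_mohm"] = r_mean
    df["resistance_min_area_mohm"] = r_min
    return df


def analyze_morphometry(df: pd.DataFrame, config: RunConfig,
                        out: Path | None = None) -> dict[str, pd.DataFrame]:
    """The full statistical battery on a per-spine table."""
    conds = sorted(df["condition"].unique())
    bundle: dict[str, pd.DataFrame] = {}

    # along-neck diameter CV comparison between conditions
    if "neck_diam_cv" in df and len(conds) == 2:
        a = df[df.condition == conds[0]]["neck_diam_cv"].dropna().to_numpy()
        b = df[df.condition == conds[1]]["neck_diam_cv"].dropna().to_numpy()
        g = ks_two_sample(a, b, labels=(conds[0], conds[1]))
        bundle["cv_comparison"] = pd.DataFrame([{
            "measurand": "neck_diam_cv",
            "cond_a": conds[0], "cond_b": conds[1],
            "mean_a": g.means[0], "mean_b": g.means[1],
            "sd_a": g.sds[0], "sd_b": g.sds[1],
            "ks_d": g.ks_d, "ks_p": g.ks_p}])

    # the six measurand distributions: K-S + shared-bin log-normal fits
    rows = []
    for m in MEASURANDS:
        if m not in df:
            continue
        pooled = df[m].dropna()
        pooled = pooled[pooled > 0]
        edges = np.histogram_bin_edges(pooled.to_numpy(float), bins="fd")
        per_cond = {}
        for c in conds:
            v = df[df.condition == c][m].dropna().to_numpy(float)
            v = v[v > 0]
            fit = fit_lognormal(v, bin_edges=edges) if len(v) >= 10 else None
            per_cond[c] = (v, fit)
        row = {"measurand": m}
        if len(conds) == 2:
            g = ks_two_sample(per_cond[conds[0]][0], per_cond[conds[1]][0],
                              labels=tuple(conds))
            row.update({"ks_d": g.ks_d, "ks_p": g.ks_p})
        for c in conds:
            v, fit = per_cond[c]
            row[f"n_{c}"] = len(v)
            row[f"mean_{c}"] = float(v.mean())
            row[f"sd_{c}"] = float(v.std(ddof=1))
            row[f"median_{c}"] = float(np.median(v))
            if fit is not None:
                row[f"lognorm_r2_{c}"] = fit.r_squared
        rows.append(row)
    bundle["distribution_comparisons"] = pd.DataFrame(rows)

    # synapse area vs head volume coupling (seeded cryo subsample)
    if "synapse_area" in df:
        cry = df[(df.condition == "cryo") & df.synapse_area.notna()
                 & df.head_volume.notna()]
        if len(cry) >= 3:
            rng = np.random.default_rng(_child_seeds(config.seed, 8)[5])
            n = min(config.synapse_n, len(cry))
            sub = cry.iloc[rng.choice(len(cry), size=n, replace=False)]
            bundle["synapse_coupling"] = pd.DataFrame([{
                "n": n,
                "r_squared": linear_r2(sub.head_volume.to_numpy(),
                                       sub.synapse_area.to_numpy()),
                "slope_um2_per_um3": float(np.polyfit(
                    sub.head_volume, sub.synapse_area, 1)[0])}])

    # Spearman correlations among the morphometric pairs
    pairs = [("neck_diam_mean", "neck_length"),
             ("neck_diam_mean", "head_volume"),
             ("head_volume", "neck_length")]
    rows = []
    for c in conds:
        sub = df[df.condition == c]
        for x, y in pairs:
            if x not in sub or y not in sub:
                continue
            s = sub[[x, y]].dropna()
            if len(s) < 3:
                continue
            r = spearman(s[x].to_numpy(), s[y].to_numpy(), variables=(x, y))
            rows.append({"condition": c, "var_x": x, "var_y": y,
                         "rho": r.rho, "p": r.p, "n": r.n})
    bundle["correlations"] = pd.DataFrame(rows)

    # condition x ER groups, one-way ANOVA + Tukey HSD
    if "er_in_neck" in df and df["er_in_neck"].notna().all() \
            and len(conds) == 2:
        rows = []
        for resp in ["neck_length", "neck_diam_mean", "head_volume"]:
            if resp not in df:
                continue
            try:
                t = tukey_er_comparison(df, resp,
                                        log_transform=config.log_transform_tukey)
            except ValueError as exc:
                log.warning("tukey on %s skipped: %s", resp, exc)
                continue
            t.insert(0, "response", resp)
            rows.append(t)
        if rows:
            bundle["er_groups"] = pd.concat(rows, ignore_index=True)

    # neck resistance comparison and its correlation with neck area
    if "resistance_mohm" in df:
        rows = []
        if len(conds) == 2:
            a = df[df.condition == conds[0]]["resistance_mohm"].dropna().to_numpy()
            b = df[df.condition == conds[1]]["resistance_mohm"].dropna().to_numpy()
            g = ks_two_sample(a, b, labels=tuple(conds))
            rows.append({"statistic": "ks", "cond_a": conds[0],
                         "cond_b": conds[1], "mean_a": g.means[0],
                         "mean_b": g.means[1], "sd_a": g.sds[0],
                         "sd_b": g.sds[1], "median_a": g.medians[0],
                         "median_b": g.medians[1], "ks_d": g.ks_d,
                         "ks_p": g.ks_p})
        for c in conds:
            sub = df[df.condition == c][["resistance_mohm",
                                         "neck_area_mean"]].dropna()
            if len(sub) >= 3:
                r = spearman(sub.resistance_mohm.to_numpy(),
                             sub.neck_area_mean.to_numpy(),
                             variables=("resistance_mohm", "neck_area_mean"))
                rows.append({"statistic": f"spearman_r_vs_area_{c}",
                             "rho": r.rho, "ks_p": r.p, "mean_a": np.nan})
        bundle["resistance_comparison"] = pd.DataFrame(rows)

    bundle["condition_summary"] = summarize_condition(df)

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        for name, table in bundle.items():
            _write_csv(table, out / f"{name}.csv")
    return bundle


def _measure_one(mesh: SpineMesh, config: RunConfig, condition: str = "",
                 modality: str = "") -> dict:
    if config.sectioned:
        mesh = sectioned_degrade(mesh, config.section_thickness,
                                 config.pixel_size)
    rec = measure_spine(mesh, config.measure_config(), condition=condition,
                        modality=modality)
    return rec.as_dict()


def run_simulated_study(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Generate, mesh, measure and analyze both condition populations."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 8)
    import dataclasses as _dc

    specs = [cryo_default_spec(config.n_cryo, seed=seeds[0]),
             chemical_default_spec(config.n_chem, seed=seeds[1])]
    specs = [_dc.replace(s, boundary_alpha=config.boundary_alpha,
                         **config.population_overrides.get(s.condition, {}))
             for s in specs]
    spec_by_cond = {s.condition: s for s in specs}

    gts = []
    for s in specs:
        gts.extend(sample_population(s))
    gt_df = ground_truth_frame(gts)
    _write_csv(gt_df, out / "ground_truth.csv")

    mesh_dir = out / "meshes"
    if config.save_meshes:
        mesh_dir.mkdir(exist_ok=True)

    records = []
    n_fail = 0
    meshes_for_sidecar = []
    for gt in gts:
        try:
            mesh = make_spine_mesh(gt, resolution=config.resolution)
            if config.save_meshes:
                write_mesh(mesh, mesh_dir / f"{gt.spine_id}.{config.mesh_format}")
                meshes_for_sidecar.append(mesh)
            rec = _measure_one(mesh, config, condition=gt.condition,
                               modality=gt.modality)
        except Exception as exc:  # noqa: BLE001
            rec = {"spine_id": gt.spine_id, "condition": gt.condition,
                   "modality": gt.modality,
                   "error": f"{type(exc).__name__}: {exc}"}
        # annotations scored at segmentation time, not measured from geometry
        rec["er_in_neck"] = gt.er_in_neck
        rec["synapse_area"] = gt.synapse_area
        if rec.get("error"):
            n_fail += 1
            log.warning("spine %s failed: %s", gt.spine_id, rec["error"])
        records.append(rec)
    if config.save_meshes and meshes_for_sidecar:
        write_base_points(meshes_for_sidecar, mesh_dir / "base_points.csv")

    if n_fail > config.max_failure_fraction * len(gts):
        raise RuntimeError(
            f"{n_fail}/{len(gts)} spines failed measurement; aborting "
            "(inspect the per-spine error column)")

    df = pd.DataFrame(records)
    df = _add_resistances(df, ResistivityModel(config.rho_ohm_cm))
    _write_csv(df, out / "morphometry.csv")

    bundle = analyze_morphometry(df, config, out=out)
    bundle["morphometry"] = df
    bundle["ground_truth"] = gt_df

    manifest = {"tool": "spinemorph", "version": __version__,
                "mode": "simulate", "seed": config.seed,
                "n_cryo": config.n_cryo, "n_chem": config.n_chem,
                "spec_conditions": sorted(spec_by_cond),
                "n_failed": n_fail,
                "config": {k: v for k, v in asdict(config).items()
                           if not isinstance(v, Path)}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    _write_summary(bundle, out / "summary.txt")
    return bundle


def run_measure(config: RunConfig, mesh_paths: list[str | Path]
                ) -> pd.DataFrame:
    """Measure a batch of user meshes (OBJ/PLY + base-point sidecar)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base_points: dict[str, np.ndarray] = {}
    for p in mesh_paths:
        sidecar = Path(p).parent / "base_points.csv"
        if sidecar.exists():
            base_points.update(read_base_points(sidecar))
    records = []
    for p in mesh_paths:
        p = Path(p)
        try:
            bp = base_points.get(p.stem)
            mesh = read_mesh(p, base_point=bp)
            rec = _measure_one(mesh, config)
        except Exception as exc:  # noqa: BLE001
            rec = {"spine_id": p.stem,
                   "error": f"{type(exc).__name__}: {exc}"}
            log.warning("mesh %s failed: %s", p, rec["error"])
        records.append(rec)
    cols = ["spine_id", "condition", "modality", "neck_length",
            "neck_area_mean", "neck_area_min", "neck_diam_mean",
            "neck_diam_min", "neck_diam_cv", "head_volume", "error"]
    df = pd.DataFrame(records, columns=cols if not records else None)
    if len(df):
        df = _add_resistances(df, ResistivityModel(config.rho_ohm_cm)) \
            if "neck_length" in df else df
    _write_csv(df, out / "morphometry.csv")
    return df


def run_reanalyze(config: RunConfig, table_path: str | Path
                  ) -> dict[str, pd.DataFrame]:
    """Recompute resistances and the statistical battery from a CSV table.

    ``config.column_map`` maps this pipeline's column names to the table's
    (e.g. ``{"neck_length": "Spine length (um)"}``) for source-data files
    with different headers.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    raw = pd.read_csv(table_path)
    if config.column_map:
        rename = {src: dst for dst, src in config.column_map.items()}
        raw = raw.rename(columns=rename)
    required = ["condition", "neck_length", "neck_area_mean"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"reanalyze table is missing columns: {missing} "
                         "(use the column_map config section)")
    df = _add_resistances(raw, ResistivityModel(config.rho_ohm_cm))
    _write_csv(df, out / "morphometry.csv")
    bundle = analyze_morphometry(df, config, out=out)
    bundle["morphometry"] = df
    return bundle


def _write_summary(bundle: dict[str, pd.DataFrame], path: Path) -> None:
    lines = ["spinemorph simulated-study summary", "=" * 40]
    f2 = bundle.get("distribution_comparisons")
    if f2 is not None:
        lines.append("\nDistribution comparisons (K-S):")
        for _, r in f2.iterrows():
            lines.append(
                f"  {r['measurand']:16s} D={r.get('ks_d', np.nan):.3f} "
                f"p={r.get('ks_p', np.nan):.2g}")
    f5 = bundle.get("resistance_comparison")
    if f5 is not None and len(f5):
        r = f5.iloc[0]
        if r.get("statistic") == "ks":
            lines.append(
                f"\nNeck resistance: {r['cond_a']} {r['mean_a']:.1f} MOhm vs "
                f"{r['cond_b']} {r['mean_b']:.1f} MOhm (K-S p={r['ks_p']:.2g})")
    f3 = bundle.get("correlations")
    if f3 is not None:
        lines.append("\nSpearman correlations:")
        for _, r in f3.iterrows():
            lines.append(f"  {r['condition']:9s} {r['var_x']} vs {r['var_y']}: "
                         f"rho={r['rho']:+.3f} p={r['p']:.2g} (n={r['n']})")
    path.write_text("\n".join(lines) + "\n")
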