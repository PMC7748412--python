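"""Synthetic spine populations with exact, known geometry.

Two fixation conditions are emulated purely through their parameter
distributions: per-spine mean neck diameter, neck length and head volume are
drawn log-normally with the condition's arithmetic mean +- SD; the radius
along each neck varies smoothly (2-3 low-order Fourier modes) with a
per-spine coefficient of variation; an ER-in-neck flag is drawn with a
probability logistic in log head volume so that +ER spines have larger
heads; synapse area is linear in head volume plus Gaussian noise.

Ground truth is *operational*: the stored neck length and head volume are
the values the boundary rule (diameter threshold ``alpha`` x the typical
neck diameter) defines on the constructed analytic profile, computed by
root finding and quadrature, so a perfect measurement would recover them
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .geometry import SpineSolid, sweep_mesh
from .meshio import MeshValidationError, SpineMesh

__all__ = [
    "PopulationSpec",
    "SpineGroundTruth",
    "lognormal_from_moments",
    "lognormal_moments",
    "sample_population",
    "make_spine_mesh",
    "cryo_default_spec",
    "chemical_default_spec",
    "ground_truth_frame",
]


# ------------------------------------------------------------------ log-normal
def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Log-normal (log_mean, log_sd) with given arithmetic mean and SD.

    Closed form: ``log_sd^2 = ln(1 + sd^2/mean^2)``,
    ``log_mean = ln(mean) - log_sd^2 / 2``.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    log_var = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - log_var / 2.0), float(np.sqrt(log_var))


def lognormal_moments(log_mean: float, log_sd: float) -> tuple[float, float]:
    """Arithmetic (mean, sd) of a log-normal; inverse of the above."""
    m = np.exp(log_mean + log_sd**2 / 2.0)
    return float(m), float(m * np.sqrt(np.expm1(log_sd**2)))


# ----------------------------------------------------------------------- types
#: truncation bounds keeping meshes resolvable; they cover the printed ranges
#: (the largest printed resistances imply mean neck diameters down to ~50 nm)
DIAM_BOUNDS = (0.05, 0.40)     # um, per-spine mean neck diameter
LEN_BOUNDS = (0.20, 3.00)      # um, neck length
VOL_BOUNDS = (0.004, 0.60)     # um^3, head volume
CV_BOUNDS = (0.02, 0.40)       # within-spine diameter CV (fraction)


@dataclass
class PopulationSpec:
    """Distribution parameters for one condition's spine population."""

    n_spines: int
    condition: str
    neck_diam_mean: float          # um (arithmetic mean of per-spine means)
    neck_diam_sd: float
    neck_len_mean: float           # um
    neck_len_sd: float
    head_vol_mean: float           # um^3
    head_vol_sd: float
    within_spine_cv: float = 0.21      # mean per-spine diameter CV (fraction)
    within_spine_cv_sd: float = 0.14   # spread of the per-spine CV
    er_prevalence: float = 0.4
    er_head_volume_multiplier: float = 2.0
    # synapse area = slope * head volume + noise; with the cryo head-volume
    # SD of ~0.074 um^3 (drawn SD plus boundary-collar variation) the noise
    # SD of 0.045 um^2 puts the coupling R^2 near 0.73
    synapse_area_slope: float = 1.0    # um^2 per um^3 head volume
    synapse_area_noise_sd: float = 0.045  # um^2
    neck_head_rho: float = 0.0     # copula corr.: ln neck diam vs ln head vol
    tem_fraction: float = 0.5      # fraction imaged by TEM (rest FIBSEM)
    bend_angle_deg: float = 30.0
    boundary_alpha: float = 1.5    # neck-boundary threshold used for ground truth
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spines < 1:
            raise ValueError("n_spines must be >= 1")
        for name in ("neck_diam_mean", "neck_len_mean", "head_vol_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("neck_diam_sd", "neck_len_sd", "head_vol_sd",
                     "within_spine_cv", "within_spine_cv_sd",
                     "synapse_area_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.er_prevalence <= 1.0:
            raise ValueError("er_prevalence must be in [0, 1]")
        if not -1.0 < self.neck_head_rho < 1.0:
            raise ValueError("neck_head_rho must be in (-1, 1)")


def cryo_default_spec(n_spines: int = 116, seed: int = 0) -> PopulationSpec:
    """Cryo-fixed condition defaults (population moments in um units)."""
    return PopulationSpec(
        n_spines=n_spines, condition="cryo",
        neck_diam_mean=0.128, neck_diam_sd=0.0628,
        neck_len_mean=0.770, neck_len_sd=0.550,
        head_vol_mean=0.069, head_vol_sd=0.062,
        within_spine_cv=0.21, within_spine_cv_sd=0.14,
        neck_head_rho=0.0, tem_fraction=89 / 116, seed=seed)


def chemical_default_spec(n_spines: int = 150, seed: int = 1) -> PopulationSpec:
    """Chemically fixed condition defaults (population moments in um units)."""
    return PopulationSpec(
        n_spines=n_spines, condition="chemical",
        neck_diam_mean=0.1824, neck_diam_sd=0.0545,
        neck_len_mean=0.836, neck_len_sd=0.569,
        head_vol_mean=0.081, head_vol_sd=0.087,
        within_spine_cv=0.15, within_spine_cv_sd=0.07,
        neck_head_rho=0.36, tem_fraction=75 / 150, seed=seed)


@dataclass
class SpineGroundTruth:
    """Constructed geometry of a single synthetic spine (lengths in um)."""

    spine_id: str
    condition: str
    modality: str
    neck_length: float             # operational (boundary-rule) neck length
    neck_mean_diameter: float      # core-neck arc-length mean diameter
    neck_min_diameter: float
    neck_area_mean: float          # pi/4 * mean d(u)^2 over the core
    neck_area_min: float
    neck_diam_cv: float            # realized RMS CV of d(u), percent
    head_radius: float
    head_volume: float             # apical of the boundary plane (quadrature)
    er_in_neck: bool
    synapse_area: float
    neck_radius_profile: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    # construction parameters needed to rebuild the identical solid
    stub_length: float = 0.3
    stub_radius: float = 0.25
    blend_width: float = 0.04
    core_length: float = 0.0
    bend_angle: float = 0.0        # radians

    def solid(self) -> SpineSolid:
        return SpineSolid(self.stub_length, self.stub_radius, self.blend_width,
                          self.core_length, self.neck_radius_profile,
                          self.head_radius, self.bend_angle)


# ------------------------------------------------------------------- sampling
def _truncated_lognormal(rng: np.random.Generator, mean: float, sd: float,
                         bounds: tuple[float, float]) -> float:
    """One log-normal draw redrawn into bounds (degenerate sd=0 is clamped)."""
    mu, sig = lognormal_from_moments(mean, sd)
    if sig == 0:
        return float(np.clip(mean, *bounds))
    for _ in range(1000):
        x = float(np.exp(rng.normal(mu, sig)))
        if bounds[0] <= x <= bounds[1]:
            return x
    return float(np.clip(x, *bounds))


def _neck_profile(rng: np.random.Generator, d0: float, cv: float
                  ) -> tuple[Callable[[np.ndarray], np.ndarray], float]:
    """Smooth Fourier radius perturbation with target RMS ``cv``.

    Modes k=2,3 (zero mean over the core) with random phases and a random
    energy split; the amplitude is capped so the minimum radius stays above
    30% of the mean (the neck must remain resolvable).  Returns
    (radius function of u in [0,1], realized cv).
    """
    if cv <= 0:
        return (lambda u: np.full_like(np.asarray(u, dtype=float), d0 / 2.0),
                0.0)
    x = rng.uniform(0.3, 0.7)
    amps = np.array([cv * np.sqrt(2 * x), cv * np.sqrt(2 * (1 - x))])
    phases = rng.uniform(0, 2 * np.pi, size=2)
    ks = np.array([2.0, 3.0])

    def eps(u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        return sum(a * np.cos(2 * np.pi * k * u + p)
                   for a, k, p in zip(amps, ks, phases))

    grid = np.linspace(0.0, 1.0, 2001)
    e = eps(grid)
    scale = 1.0
    if 1.0 + e.min() * scale < 0.30:
        scale = 0.70 / abs(e.min())
    realized_cv = float(np.sqrt(np.mean((scale * e) ** 2)))

    def radius(u: np.ndarray) -> np.ndarray:
        return (d0 / 2.0) * (1.0 + scale * eps(u))

    return radius, realized_cv


def _calibrate_core_length(build: Callable[[float], SpineSolid],
                           target_len: float, threshold: float) -> SpineSolid:
    """Choose the core length so the operational neck length equals target.

    The operational length (distance between the outer threshold crossings)
    is affine in the core length, ``f(Lc) = g Lc + delta``; two evaluations
    give g and delta exactly.
    """
    def op_len(lc: float) -> float:
        s = build(lc)
        lo, hi = s.threshold_crossings(threshold)
        return hi - lo

    f1, f2 = op_len(1.0), op_len(2.0)
    g = f2 - f1
    delta = f1 - g
    if g <= 0.05:
        lc = max(target_len, 0.05)
    else:
        lc = max((target_len - delta) / g, 0.05)
    return build(lc)


def _er_logistic(v: np.ndarray, prevalence: float, multiplier: float
                 ) -> np.ndarray:
    """Per-spine ER probabilities, logistic in ln(head volume).

    The slope is calibrated so the expected +ER/-ER head-volume mean ratio
    equals ``multiplier``; the intercept so the expected prevalence matches.
    """
    if prevalence <= 0:
        return np.zeros_like(v)
    if prevalence >= 1:
        return np.ones_like(v)
    z = np.log(v)
    zc = z - z.mean()

    def probs(b: float, b0: float) -> np.ndarray:
        return expit(b0 + b * zc)

    def solve_b0(b: float) -> float:
        return brentq(lambda b0: probs(b, b0).mean() - prevalence, -30, 30)

    def ratio(b: float) -> float:
        p = probs(b, solve_b0(b))
        hi = (p * v).sum() / p.sum()
        lo = ((1 - p) * v).sum() / (1 - p).sum()
        return hi / lo

    if multiplier <= 1.0 or np.ptp(z) < 1e-9:
        return np.full_like(v, prevalence)
    b_hi = 20.0
    if ratio(b_hi) < multiplier:   # cannot reach the target separation
        b = b_hi
    else:
        b = brentq(lambda bb: ratio(bb) - multiplier, 1e-6, b_hi)
    return probs(b, solve_b0(b))


def sample_population(spec: PopulationSpec) -> list[SpineGroundTruth]:
    """Draw a deterministic population of constructed spine geometries."""
    rng = np.random.default_rng(spec.seed)
    mu_d, sig_d = lognormal_from_moments(spec.neck_diam_mean, spec.neck_diam_sd)
    mu_v, sig_v = lognormal_from_moments(spec.head_vol_mean, spec.head_vol_sd)
    rho = spec.neck_head_rho

    spines: list[SpineGroundTruth] = []
    for i in range(spec.n_spines):
        # correlated (diameter, head volume) via a Gaussian copula, jointly
        # redrawn into bounds; neck length independent
        for _ in range(1000):
            z1, z2 = rng.standard_normal(2)
            z2 = rho * z1 + np.sqrt(1 - rho**2) * z2
            d0 = float(np.exp(mu_d + sig_d * z1)) if sig_d > 0 else spec.neck_diam_mean
            vol = float(np.exp(mu_v + sig_v * z2)) if sig_v > 0 else spec.head_vol_mean
            ok = (DIAM_BOUNDS[0] <= d0 <= DIAM_BOUNDS[1]
                  and VOL_BOUNDS[0] <= vol <= VOL_BOUNDS[1])
            if ok:
                break
        else:
            d0 = float(np.clip(d0, *DIAM_BOUNDS))
            vol = float(np.clip(vol, *VOL_BOUNDS))
        rh = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
        length = _truncated_lognormal(rng, spec.neck_len_mean, spec.neck_len_sd,
                                      LEN_BOUNDS)
        if spec.within_spine_cv_sd > 0 and spec.within_spine_cv > 0:
            cv = -1.0
            for _ in range(1000):
                cv = rng.normal(spec.within_spine_cv, spec.within_spine_cv_sd)
                if CV_BOUNDS[0] <= cv <= CV_BOUNDS[1]:
                    break
            cv = float(np.clip(cv, *CV_BOUNDS))
        else:
            cv = spec.within_spine_cv

        radius_fn, realized_cv = _neck_profile(rng, d0, cv)
        grid = np.linspace(0.0, 1.0, 2001)
        d_of_u = 2.0 * radius_fn(grid)
        d_min = float(d_of_u.min())
        # the head must rise above the boundary threshold and beyond the
        # junction radius; enlarge the rare marginal head rather than
        # rejecting (rejection would couple head volume to neck diameter)
        # 1.3 x the threshold radius: a head that barely grazes the boundary
        # threshold would put the neck/head crossing on a nearly flat flare,
        # where its position (and hence head volume) is ill-conditioned
        r_need = max((spec.boundary_alpha * d_min / 2.0) * 1.3,
                     float(radius_fn(np.array([1.0]))[0]) * 1.05)
        rh = max(rh, r_need)
        stub_radius = max(0.22, 0.9 * d0)
        stub_length = max(0.25, 1.1 * stub_radius)

        def build(lc: float, _r=radius_fn, _rh=rh, _sr=stub_radius,
                  _sl=stub_length) -> SpineSolid:
            return SpineSolid(_sl, _sr, 0.04, lc, _r, _rh,
                              np.deg2rad(spec.bend_angle_deg))

        # boundary threshold: alpha x the typical (median) core diameter,
        # the robust waist scale the measurement side estimates from its
        # stations; for a uniform neck this is alpha x the minimum
        d_typ = float(np.median(d_of_u))
        threshold = spec.boundary_alpha * d_typ
        solid = _calibrate_core_length(build, length, threshold)
        lo, hi = solid.threshold_crossings(threshold)

        modality = "TEM" if rng.uniform() < spec.tem_fraction else "FIBSEM"
        head_vol = float(solid.volume_between(hi, solid.t_apex))
        syn = spec.synapse_area_slope * head_vol
        syn = max(float(syn + rng.normal(0.0, spec.synapse_area_noise_sd)), 0.0)

        # operational neck statistics: continuous arc-length statistics of
        # the diameter over the boundary-to-boundary window (including the
        # sub-threshold flare shoulders the rule assigns to the neck), i.e.
        # exactly what a perfect measurement of the measurand returns
        t_neck = np.linspace(lo, hi, 1501)
        d_neck = solid.diameter(t_neck)

        spines.append(SpineGroundTruth(
            spine_id=f"{spec.condition}_{i:03d}",
            condition=spec.condition,
            modality=modality,
            neck_length=float(hi - lo),
            neck_mean_diameter=float(d_neck.mean()),
            neck_min_diameter=float(d_neck.min()),
            neck_area_mean=float(np.pi / 4.0 * np.mean(d_neck**2)),
            neck_area_min=float(np.pi / 4.0 * d_neck.min()**2),
            neck_diam_cv=100.0 * float(d_neck.std() / d_neck.mean()),
            head_radius=float(rh),
            head_volume=head_vol,
            er_in_neck=False,          # filled below from the joint sample
            synapse_area=syn,
            neck_radius_profile=radius_fn,
            stub_length=stub_length,
            stub_radius=stub_radius,
            blend_width=0.04,
            core_length=solid.core_length,
            bend_angle=np.deg2rad(spec.bend_angle_deg),
        ))

    # ER flags: probability increases with head volume (logistic in log V)
    vols = np.array([s.head_volume for s in spines])
    p_er = _er_logistic(vols, spec.er_prevalence,
                        spec.er_head_volume_multiplier)
    flags = rng.uniform(size=len(spines)) < p_er
    for s, f in zip(spines, flags):
        s.er_in_neck = bool(f)
    return spines


# -------------------------------------------------------------------- meshing
def make_spine_mesh(gt: SpineGroundTruth, resolution: float | None = None,
                    n_theta: int = 28) -> SpineMesh:
    """Triangulate one ground-truth spine as a closed 2-manifold surface.

    ``resolution`` is the axial ring spacing; it must be at most a quarter
    of the minimum neck diameter (default: min diameter / 4.2, clipped to
    [3.5, 10] nm).
    """
    if resolution is None:
        resolution = float(np.clip(gt.neck_min_diameter / 4.2, 0.0035, 0.010))
    if resolution > gt.neck_min_diameter / 4.0:
        raise ValueError(
            f"resolution {resolution} um cannot resolve a neck of minimum "
            f"diameter {gt.neck_min_diameter} um (need <= min/4)")
    solid = gt.solid()
    verts, faces = sweep_mesh(solid, resolution, n_theta=n_theta)
    mesh = SpineMesh(verts, faces, solid.axis.point(0.0)[0], gt.spine_id)
    mesh.validate()
    tm = mesh.trimesh
    if not (tm.is_watertight and tm.is_winding_consistent
            and tm.euler_number == 2):
        raise MeshValidationError(
            f"constructed mesh for {gt.spine_id} is not a closed genus-0 "
            "2-manifold")
    return mesh


def ground_truth_frame(spines: list[SpineGroundTruth]) -> pd.DataFrame:
    """Per-spine ground-truth table mirroring the measured CSV layout."""
    rows = []
    for s in spines:
        rows.append({
            "spine_id": s.spine_id,
            "condition": s.condition,
            "modality": s.modality,
            "neck_length": s.neck_length,
            "neck_area_mean": s.neck_area_mean,
            "neck_area_min": s.neck_area_min,
            "neck_diam_mean": s.neck_mean_diameter,
            "neck_diam_min": s.neck_min_diameter,
            "neck_diam_cv": s.neck_diam_cv,
            "head_volume": s.head_volume,
            "er_in_neck": s.er_in_neck,
            "synapse_area": s.synapse_area,
        })
    return pd.DataFrame(rows)
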