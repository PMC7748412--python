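# Methods

`spinemorph` measures the geometry of single dendritic spines from closed
triangulated surface meshes and compares populations of such measurements
between tissue-preparation conditions. This note documents the models,
algorithms, parameter choices and known limitations.

## The measurement model

A spine is treated as a genus-0 solid: a bulbous head joined to the parent
dendrite by a narrow neck. All quantities derive from a **centerline** — an
ordered polyline from the dendrite junction (the annotated base point) to the
point of maximal interior distance inside the head (the head center) — and
from **cross-sections**: planar cuts perpendicular to the local centerline
tangent. Every cross-section records the area `X_i` of the closed
intersection loop that encloses the centerline point (other loops, e.g. a cut
through the head while sectioning the neck, are ignored) and the equivalent
circular diameter `Y_i = 2 sqrt(X_i / pi)`.

Units are micrometres throughout (areas µm², volumes µm³); resistances are
reported in MΩ.

### Centerline extraction

1. The solid interior is rasterized onto an isotropic voxel grid
   (default pitch 15 nm; thin necks trigger a second pass at
   `min diameter / 6`, floored at 5 nm and capped so the grid stays below
   ~4·10⁶ voxels). Rasterization is a scanline parity fill of the planar
   mesh cuts, with the grid origin offset by an irrational fraction of the
   pitch so cut planes can never coincide with vertex lattices (exact
   coincidences break the parity count).
2. The interior is thinned to a curve skeleton (3-D topological thinning).
3. On the skeleton's voxel adjacency graph, the path runs from the voxel
   nearest the base point to the deepest voxel (interior-distance maximum)
   in the geometrically far half of the skeleton — the head center. Path
   cost is *medialness-weighted* (step length divided by interior depth) so
   that, where thinning leaves sheet-like remnants inside wide structures,
   the route follows sheet centers. Endpoint selection uses plain geometric
   distance; a medialness-weighted "far half" would be distorted.
4. The path is smoothed with a chord-length-parameterized smoothing spline
   (tolerance ~0.8 voxel), then refined by four rounds of cross-section
   recentring (each point moved to the area centroid of its own
   perpendicular section) alternated with light moving-average smoothing.
   Inside the head every chord through the center is equally medial, so the
   in-head tail is re-straightened each round; otherwise head ambiguity
   leaks into the neck tangents through the smoothing.

On analytic test tubes this recovers the construction axis to a few
nanometres in the neck and the arc length of the neck window to well under
1%.

### Neck boundaries

The neck/head and neck/dendrite boundaries are where the profile "expands
significantly". Operationally: stations are profiled every 150 nm (the
classic spacing; short necks fall back to a finer spacing so the neck spans
at least 8 stations), and the neck is the outermost run of stations whose
equivalent diameter is at most `alpha` times the **typical neck diameter**,
with `alpha = 1.5` by default and exposed in the configuration. The typical
neck diameter is the median of the stations below the geometric mean of the
global minimum and maximum station diameters. For a uniform neck this
equals the global minimum, so the rule reduces to the familiar
"1.5 × minimum" threshold; unlike the raw minimum it is not dragged down by
the deep local constrictions that along-neck diameter variation (CV ~ 20%)
produces, which would otherwise collapse the detected neck onto its deepest
dip. Interior stations poking above the threshold are bridged — they are
narrow neck, not head or dendrite. The boundary position is then refined to
the continuous threshold crossing by bisection on fresh plane sections.

Because the boundary is thresholded, the *neck window* includes short
sub-threshold flare shoulders on both sides. All neck statistics are defined
over this window:

- **neck length** — centerline arc length between the refined boundaries;
- **mean/min neck area and diameter** — unweighted mean and minimum over
  stations placed on a *midpoint partition* of the window (stations at cell
  midpoints of equal arc-length cells), so the unweighted station mean is
  the midpoint-rule estimate of the continuous along-neck mean. With
  free-running stations a single station landing on a steep flare shoulder
  would carry the full 1/n weight and bias a short spine's mean by up to
  10%;
- **CV** — 100 × sample SD / mean of the station diameters;
- **head volume** — volume of the mesh apical of the boundary plane at the
  neck end. The mesh is cut open by that plane and the volume evaluated by
  signed-tetrahedron summation with the reference origin *on* the plane,
  which closes the region exactly as the planar cap would (no triangulation
  engine needed).

### Neck resistance

Ohm's law with cytosolic resistivity ρ = 109 Ω·cm (configurable):
`R = ρ L / A` with the per-spine *mean* neck area — the headline statistic —
plus two labelled variants for sensitivity analysis: the minimum-area form
and a discretized series integral `R = Σ ρ (L/n) / X_i` over the midpoint
stations, which equals the mean-area form for a uniform neck and exceeds it
for any varying profile (AM–HM inequality). The variants bracket the
uncertainty left by not knowing which area statistic best represents a real
neck partially obstructed by organelles. `1 Ω·cm = 10⁴ Ω·µm`, so
`R(L = 1 µm, A = 1 µm², ρ = 109 Ω·cm) = 1.09 MΩ`, and a 1 GΩ neck drops
1 mV per pA of synaptic current.

## The synthetic-spine generator

The generator emulates the *study conditions*: two populations ("cryo" and
"chemical") that differ only in their parameter distributions.

Defaults (arithmetic mean ± SD, sampled log-normally with the closed-form
moment map `log_sd² = ln(1 + sd²/mean²)`, `log_mean = ln mean − log_sd²/2`):

| parameter | cryo | chemical |
|---|---|---|
| n spines | 116 | 150 |
| mean neck diameter (µm) | 0.128 ± 0.0628 | 0.1824 ± 0.0545 |
| neck length (µm) | 0.770 ± 0.550 | 0.836 ± 0.569 |
| head volume (µm³) | 0.069 ± 0.062 | 0.081 ± 0.087 |
| within-spine diameter CV | 0.21 ± 0.14 | 0.15 ± 0.07 |
| neck-diameter / head-volume coupling (copula ρ) | 0.0 | 0.36 |
| TEM fraction (rest FIBSEM) | 89/116 | 0.5 |

Draws are redrawn into truncation bounds (mean diameter 0.05–0.40 µm, neck
length 0.20–3.0 µm, head volume 0.004–0.60 µm³, CV 0.02–0.40) that keep
meshes resolvable while covering the observed ranges (the largest reported
neck resistances imply mean-area diameters near 50 nm); the resulting moment
shift is below one standard error at the default sample sizes.

Each spine is a surface of revolution swept along a planar circular arc
(default total bend 30°, so centerline extraction is tested on curved
geometry): a dendrite stub (cylinder, radius ≥ 0.22 µm), a smoothstep blend,
a neck whose radius follows 2 Fourier modes (k = 2, 3, random phases and
energy split, RMS amplitude = the spine's CV, rescaled if the minimum radius
would fall below 30% of the mean), and a spherical head truncated where its
profile continues the neck radius. Heads are enlarged, rarely, to at least
1.3× the boundary-threshold radius — a head that barely grazes the threshold
would put the neck/head crossing on a nearly flat flare where its position
is ill-conditioned. Ring vertices are radially inflated by
`sqrt(2π / (n sin(2π/n)))` so every n-gon ring has exactly the intended
cross-sectional area, removing the leading polygonization bias from areas
and volumes.

**Ground truth is operational.** The stored neck length, head volume and
neck diameter statistics are the values the boundary rule defines on the
constructed *analytic* radius profile (threshold crossings by root finding,
volumes by quadrature, window statistics by dense arc-length sampling), so a
perfect measurement recovers them exactly. The constructed core length is
calibrated (the operational length is affine in it) so the operational neck
length equals the drawn log-normal value.

Annotations: the ER-in-neck flag is Bernoulli with probability logistic in
log head volume; the slope is calibrated at sampling time so the expected
+ER/−ER head-volume ratio matches a configurable multiplier (default 2) and
the intercept so the expected prevalence matches (default 0.4 — chosen as a
realistic mid-range since only group sizes, not prevalences, are reported).
Synapse area is `1.0 µm²/µm³ × head volume` plus Gaussian noise
(SD 0.045 µm²), truncated at zero; with the cryo head-volume SD of
~0.074 µm³ this puts the coupling R² near 0.73.

### Serial-section degradation

`sectioned_degrade` emulates anisotropic serial-section sampling: the solid
is rasterized at (pixel, pixel, section) voxels — default 10 nm pixels,
50 nm sections, z the sectioning axis — with binary in-plane sampling and
*fractional* slab occupancy (sub-slices averaged through each section), then
re-meshed by marching cubes at the 0.5 level, which reconstructs the
z-profile with sub-section accuracy instead of a hard staircase. The axis
bend lies in the x–z plane so a neck sweeps through several section phases.
Remaining accuracy limits are physical: a 65 nm neck sampled with 50 nm
sections reads ~9% thin.

### What the generator does not emulate

No image formation (noise, staining, membrane contrast), no registration
error, no segmentation subjectivity, no fixation mechanism — the conditions
differ only by their parameter distributions, and ER flags/synapse areas are
carried as annotations rather than measured from geometry. Passing
recovery tests therefore validates the *measurement chain* on idealized
membranes, not robustness to real EM artifacts beyond anisotropic sampling.

## Statistics

Two-sided, unpaired two-sample Kolmogorov–Smirnov tests compare conditions
(asymptotic p by default, exact available for small n); Spearman rank
correlations (average ranks for ties) use exact permutation enumeration for
n ≤ 9 and the t-approximation otherwise; log-normal fits are maximum
likelihood on ln x with a binned R² (Freedman–Diaconis edges on the pooled
two-condition sample so conditions share bins); the ER analysis is a
one-way ANOVA over the four condition × ER groups followed by Tukey HSD on
raw responses (a log-transform switch exists because head volumes are
log-normal). Reported R² for the synapse-area coupling uses ordinary least
squares on a seeded subsample of 33 cryo spines, matching the analysis size
the coupling is defined against.

## Pipeline and reproducibility

Three modes compose: `simulate` = generate + mesh + measure + analyze;
`measure` runs the measurement chain on user OBJ/PLY meshes with a
base-point sidecar CSV; `reanalyze` recomputes resistances and every
statistic from a per-spine CSV alone (a `column_map` section adapts foreign
headers). All randomness flows from one root seed through
`numpy.random.SeedSequence` children; identical (config, seed) runs produce
byte-identical CSVs. Per-spine failures are recorded on the row and skipped;
a run aborts only if more than 5% of spines fail.

Default problem sizes: populations of 116 + 150 spines (~0.7 s per spine on
one core), a 50-spine recovery panel spanning the 15th–85th percentiles of
each printed parameter distribution (clean and degraded), 2000-replicate
K-S and 800-replicate Tukey null calibrations.

## Numerical choices and edge cases

- Ties in the minimum-area station: the first station from the base wins
  (`argmin` order).
- Spines shorter than one station spacing fall back to quarter-length
  spacing and are flagged `stubby_spacing`; monotone profiles (no waist) are
  flagged `no_waist` and return the full range; centerline excursions and
  sharp turns (> 60°) are flagged, and a finer-pitch centerline pass is
  accepted only if it does not introduce such flags.
- The reanalyze mode cannot compute the series-integral resistance variant
  (no profile); the column is left empty there.
- `MAX_VOXELS` (4·10⁸) bounds any rasterization; exceeding it raises with
  advice to coarsen sampling.

## Known limitations

- Single base and single head: branched spines, spinules and multi-synapse
  geometries are out of scope.
- The along-neck CV measured from ~5–10 stations is a small-sample SD; its
  population mean runs ~5–10% below the generating RMS amplitude, and the
  boundary flare shoulders add a point or two for thick short necks.
- Population medians of derived ratios (e.g. neck resistance) are sensitive
  to the assumed independence of neck length and area; with independent
  log-normal marginals the model median is below what correlated real data
  can produce even when the means match.
- Mesh-based measurements assume closed, self-intersection-free surfaces;
  validation rejects open or non-manifold input rather than repairing it.
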