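# spinemorph

Morphometry of dendritic spines from triangulated surface meshes.

Dendritic spines — the micron-scale protrusions that carry most excitatory
synapses — couple their synapse to the parent dendrite through a thin neck
whose geometry sets both diffusional and electrical resistance. Studies that
reconstruct spines from serial electron microscopy need a reproducible way
to turn a closed surface mesh into the standard per-spine record: head
volume, neck length, mean and minimum neck cross-sectional area and
diameter, the along-neck diameter variation, and the implied neck
resistance. `spinemorph` implements that measurement chain and the
population statistics used to compare preparation conditions (e.g.
cryo-fixed vs chemically fixed tissue), together with a synthetic-spine
generator whose exact constructive ground truth validates every step.

The core quantities, for cross-sections `X_1 … X_n` taken perpendicular to
a base-to-head centerline at regular stations:

- equivalent diameters `Y_i = 2 √(X_i / π)`;
- neck boundaries where the profile expands significantly (threshold
  `α = 1.5 ×` the typical neck diameter);
- neck statistics `mean(X_i)`, `min(X_i)`, `mean(Y_i)`, `min(Y_i)`,
  `CV = 100·sd(Y_i)/mean(Y_i)` over the neck window;
- head volume apical of the neck/head boundary plane;
- neck resistance `R = ρ L / A` with cytosolic resistivity
  `ρ = 109 Ω·cm` (so `R(L=1 µm, A=1 µm²) = 1.09 MΩ`), plus minimum-area
  and series-integral variants.

See `docs/methods.md` for the algorithms and modeling choices.

## Worked example

Generate a small cryo-condition population, mesh and measure one spine:

```python
import spinemorph as sm

spines = sm.sample_population(sm.cryo_default_spec(n_spines=3, seed=11))
gt = spines[0]
mesh = sm.make_spine_mesh(gt)              # closed genus-0 surface, µm
rec = sm.measure_spine(mesh)

print(f"neck length   {rec.neck_length:.3f} µm   (truth {gt.neck_length:.3f})")
print(f"mean diameter {rec.neck_diam_mean*1e3:.1f} nm "
      f"(truth {gt.neck_mean_diameter*1e3:.1f})")
print(f"head volume   {rec.head_volume:.4f} µm³  (truth {gt.head_volume:.4f})")
print(f"resistance    {rec.resistance_mohm:.1f} MΩ")
```

prints

```
neck length   1.371 µm   (truth 1.376)
mean diameter 116.9 nm (truth 117.1)
head volume   0.1459 µm³  (truth 0.1460)
resistance    136.5 MΩ
```

— the measured record recovers the constructed geometry to well under a
percent here, and the 137 MΩ means roughly 2.7 mV of head-to-dendrite
potential drop per 20 pA of synaptic current.

The full two-condition study (116 cryo + 150 chemically fixed spines:
generate → mesh → measure → statistics) runs from the shell:

```sh
spinemorph simulate --seed 1 --out study_out
```

writing per-spine tables (`ground_truth.csv`, `morphometry.csv`), one CSV
per analysis (distribution comparisons with log-normal fits and
Kolmogorov–Smirnov p-values, Spearman correlation matrix, ER-group Tukey
comparison, resistance summary), and a plain-text summary. With the default
conditions the cryo population shows ~35% thinner necks (K-S p < 10⁻⁹) and
~2.4× higher mean neck resistance than the chemical population, while neck
length and head volume do not differ (p > 0.3) — and only the chemical
population couples neck diameter to head volume (Spearman ρ ≈ 0.33).

`spinemorph measure *.obj` applies the measurement chain to your own
meshes (µm coordinates, with a `base_points.csv` sidecar marking each
dendrite junction), and `spinemorph reanalyze table.csv` recomputes
resistances and all statistics from a per-spine table without any meshes.

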