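# vesiclekit

Quantitative morphometry of COPII transport vesicles and an excluded-volume
model of cargo crowding in their lumen.

COPII vesicles bud from the endoplasmic reticulum carrying secretory cargo
while largely excluding ER-resident proteins. One contribution to that
sorting stringency is purely biophysical: actively recruited cargo lines the
vesicle lumen and shrinks the space available to nonselective "bulk flow"
capture, and a bulk-flow particle of finite size is further disfavoured by an
excluded-volume effect that sharpens as vesicles get smaller. `vesiclekit`
implements both halves of the quantitative argument:

- **Morphometry** of segmented vesicle surfaces (3D point clouds or
  triangulated meshes, coordinates in nm): centroid, maximum radius/diameter,
  enclosed volume by the signed-tetrahedron (divergence) sum, and
  sphere-equivalent radius, with population medians, percentile-bootstrap 95%
  confidence intervals, percent differences between strains, and a
  permutation test on medians.
- **Occupancy/partitioning model.** For a vesicle of radius *R* the lumenal
  radius is *R* − *t*<sub>bilayer</sub> (default 4 nm); subtracting the
  coat-selected cargo layer — the fraction-weighted mean diameter of the
  recruited cargo species, each treated as a compact sphere of radius
  *r* = 0.066 nm · (*M*/Da)<sup>1/3</sup> — gives the available radius
  *R*<sub>av</sub> and volume *V*<sub>av</sub> = 4/3·π·*R*<sub>av</sub>³. A
  bulk-flow probe of radius *r*<sub>cargo</sub> partitions between vesicle
  and bulk with coefficient

  *K* = *V*<sub>eff</sub>/*V*<sub>av</sub> = (1 − *r*<sub>cargo</sub>/*R*<sub>av</sub>)³,  clipped to 0 for *r*<sub>cargo</sub> ≥ *R*<sub>av</sub>,

  classified into relaxed (*R*<sub>av</sub> ≫ *r*<sub>cargo</sub>),
  stringent (comparable scales), and excluded (*r*<sub>cargo</sub> ≥
  *R*<sub>av</sub>) regimens.
- **Synthetic vesicle generator** with known ground truth: near-spherical
  (optionally ellipsoidal) surfaces sampled like manual contour tracing,
  with radial noise and snapping to a 1.1 nm isotropic voxel grid, and four
  built-in strain presets anchored to measured population medians (WT max
  diameter 52 nm; *emp24*Δ 54 nm; *sec13*Δ *emp24*Δ 18% larger than WT with a
  broader spread; *emp24*Δ *lst1*Δ median volume 31,493 nm³).
- **Monte-Carlo oracles** that verify the analytic *K* by direct
  uniform-in-sphere sampling and the mesh volume by a ray-crossing-parity
  inside test, plus an end-to-end parameter-recovery harness.

See `docs/methods.md` for model assumptions, parameter defaults, and
numerical choices.

## Worked example

Generate a 200-vesicle population from the small-vesicle double-mutant
preset, measure it, and push the median through the partitioning model:

```python
import vesiclekit as vk

preset = vk.preset_by_name("lst1emp24", n_vesicles=200, seed=42)
surfaces = vk.generate_strain(preset)
table = vk.measure_population(surfaces)
summary = vk.summarize_population(table["volume_nm3"], n_boot=2000, seed=42)
print(f"median volume: {summary.median:.0f} nm^3  (95% CI {summary.ci95[0]:.0f}-{summary.ci95[1]:.0f})")

r = vk.sphere_equivalent_radius(summary.median)
occ = vk.occupancy(r, vk.default_cargo_mixes()["lst1emp24"])
print(f"sphere-equivalent radius: {r:.2f} nm")
print(f"lumenal radius: {occ.lumenal_radius:.2f} nm   available radius R_av: {occ.available_radius:.2f} nm")

for probe in vk.default_probe_cargoes():
    rc = probe.effective_radius(vk.ModelParams())
    res = vk.partition_coefficient(rc, occ.available_radius)
    print(f"{probe.name}: r_cargo = {rc:.2f} nm  K = {res.K:.3f}  ({res.regimen})")

mc = vk.mc_partition(6.60, occ.available_radius, n=100_000, seed=42)
print(f"Monte-Carlo check of K for the Kar2 complex: {mc.estimate:.3f} +- {mc.standard_error:.3f}")
```

Output:

```
median volume: 32358 nm^3  (95% CI 30788-33572)
sphere-equivalent radius: 19.77 nm
lumenal radius: 15.77 nm   available radius R_av: 10.91 nm
Cp: r_cargo = 2.00 nm  K = 0.545  (stringent)
Kar2 complex: r_cargo = 6.60 nm  K = 0.062  (stringent)
Monte-Carlo check of K for the Kar2 complex: 0.060 +- 0.001
```

The recovered median volume sits near the 31,493 nm³ anchor of the preset
(inside its bootstrap CI). A small inert probe like Cp (2 nm) still samples
more than half the available volume (*K* ≈ 0.55), while a ~1 MDa
chaperone–client complex (6.6 nm) is almost excluded (*K* ≈ 0.06) — both in
the stringent regimen, where *K* responds to small changes in vesicle size.
The independent Monte-Carlo estimate agrees with the closed form within
sampling error.

## Command line

```sh
vesiclekit simulate --preset WT --n-vesicles 100 --seed 1 --out out/sim
vesiclekit morphometry --points out/sim/WT_points.csv --reference-strain WT --out out/morph
vesiclekit model --reference WT --grid 2:20:0.5,0.5:10:0.25 --out out/model
vesiclekit oracle partition --r 6.6 --R 13.2 --n 100000 --seed 1
vesiclekit run --seed 1 --out out/full-run
```

`run` executes the full chain (simulate → morphometry → model → oracle spot
check) and writes TSV tables plus a `manifest.json` that suffices to re-run
the pipeline bit-identically.

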