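# Methods

## Morphometry of segmented vesicle surfaces

A segmented vesicle arrives as a point cloud (nm) or a triangulated mesh.
The centroid (arithmetic mean of the surface points) estimates the vesicle
center; the **maximum radius** is the largest Euclidean distance from the
centroid to any surface point, and the maximum diameter is twice that.
Coordinates supplied in voxel units are scaled by the voxel edge (default
1.1 nm isotropic) before measuring.

The **enclosed volume** of a closed, consistently oriented triangle mesh is
the absolute value of the signed-tetrahedron sum Σ det(a, b, c)/6 over its
triangles (divergence theorem). Closedness is checked by counting directed
boundary edges; an open mesh raises an error naming the count. For a bare
point cloud the documented fallback is the convex-hull volume — vesicle
surfaces are near-convex, so the hull approximates the enclosed volume well.
The **sphere-equivalent radius** of a volume V is (3V/4π)^(1/3).

Two deliberate measurement properties, shared with manual segmentation
workflows, are documented rather than corrected:

- The maximum radius is an extreme-value statistic. With radial tracing
  noise σ, voxel snapping, and the centroid estimated from the same n
  points, it overestimates the true radius — at the default sampling density
  (150 points/vesicle, σ = 0.5 nm, 1.1 nm voxels, ~25 nm radius) by roughly
  2.5 nm. Measurements are reported from the snapped coordinates as-is.
- The convex hull of a finite sample slightly underestimates the enclosed
  volume (chords cut inside the surface), partially offset by outward noise.

Population summaries report the **median** (midpoint convention for even n)
with a **percentile-bootstrap 95% CI of the median**: resample with
replacement n_boot times (default 2000; ≥ 100 enforced), take the 2.5/97.5
percentiles of the bootstrap medians. Strain contrasts are signed percent
differences of medians, 100·(other − reference)/reference, with an optional
two-sided permutation test on the median difference (default 10,000
permutations, fixed seed). Parametric multiple-comparison machinery (ANOVA
with post-hoc corrections) is intentionally not used: bootstrap and
permutation procedures are distribution-free and keep the pipeline
self-contained.

## Synthetic vesicle generator

The generator emulates segmented surfaces of free COPII vesicles, not
tomograms: n points are placed in approximately uniform random directions on
an ellipsoid with semi-axes radius · axial_ratios (sphere by default),
perturbed radially by Gaussian noise, then snapped coordinate-wise to the
voxel grid. Random (rather than regular) placement mimics the variability of
manually clicked contours and makes bootstrap statistics on synthetic
populations behave like they do on real measurements. Defaults: 150
points/vesicle (a ~50 nm vesicle traced every fifth 1.1 nm slice with ~17
clicks per contour), tracing noise 0.5 nm, isotropic 1.1 nm voxel. Ellipsoid
deformation is the only non-sphericity mode — enough to decouple the maximum
radius from the sphere-equivalent radius; arbitrary blob shapes are out of
scope. Ground truth (largest semi-axis, analytic volume 4/3·π·abc) rides
along on every synthetic surface.

Populations draw vesicle radii i.i.d. from a lognormal (default) or
positive-truncated normal distribution. Reported size data constrain only
the range and median per strain, not the family; lognormal is a modelling
choice (strictly positive, mildly right-skewed), recorded in config rather
than asserted as fact.

**Seeding.** One root seed per run; child seed i is
`SeedSequence(root, spawn_key=(i,)).generate_state(1)[0] & 0x7FFFFFFF`.
Counter 0 draws the radii, counter k (1-based) seeds vesicle k, so any
vesicle is regenerable from (root, k) alone. Fixed seed ⇒ bit-identical
output.

**Preset calibration.** The four built-in presets are anchored to measured
population medians (WT 52 nm and emp24del 54 nm max diameter; sec13del
emp24del 52·1.18 nm with log-sd 0.14 vs 0.08 elsewhere; emp24del lst1del
median volume 31,493 nm³). Because the measured quantities carry the
sampling biases above, each preset's latent radius median is placed where
the *measured* median reproduces the anchor: a deterministic internal
Monte-Carlo run (fixed internal seed, 200 reference vesicles, two
fixed-point iterations; multiplicative update with exponent 1 for diameter
targets and 1/3 for volume targets) estimates the bias. The calibration is
part of the generator, cached, and independent of user seeds.

## Occupancy and partitioning model

The vesicle is a sphere of radius R (by default the sphere-equivalent radius
of a strain's median volume; a maximum-diameter/2 input is possible but
mixes two differently biased measures — the discrepancy is why both are
reported separately by the morphometry stage). The chain is:

    lumenal radius = R − bilayer (default 4 nm)
    R_av = lumenal radius − cargo layer
    V_av = 4/3 π R_av³

The **cargo layer** is the fraction-weighted mean *diameter* of the
coat-selected cargo species. Default mixes: WT = 25% p24/GPI-AP complexes
(100 kD) + 75% average secretory cargo (50 kD); strains lacking Emp24 keep
only the model cargo. A species' radius comes from its molecular weight by
the compact-sphere scaling r = c·M^(1/3) with c = 0.066 nm·Da^(−1/3) (an
unhydrated minimal protein sphere, ~1.37 g/cm³); c is configurable because
density/hydration assumptions legitimately vary. Species may instead carry
an explicit radius — used for the Cp bulk-flow probe (default 2.0 nm, a
configurable stand-in for a hydrodynamic computation that is outside this
package's scope) — and a Kar2/client chaperone complex is modelled as a
1 MDa sphere (r = 6.6 nm).

A probe of radius r_cargo can centre itself only within R_eff = R_av −
r_cargo, so K = V_eff/V_av = (1 − r_cargo/R_av)³, clipped to exactly 0 for
r_cargo ≥ R_av (the raw cube would be negative). Regimens: **excluded** if
r_cargo ≥ R_av; **relaxed** if R_av/r_cargo ≥ 10 (the threshold for "much
larger" is a reporting convention, surfaced in output metadata so
classifications are auditable); **stringent** otherwise. This is the dilute
hard-sphere-in-a-sphere limit: no finite packing, cargo–cargo interaction,
or capture kinetics.

From the closed form, ∂(ln K)/∂R_av = 3·r_cargo/(R_av(R_av − r_cargo)): at
fixed R_av the relative sensitivity of K to vesicle size grows with cargo
size, which is the model's central qualitative claim — larger bulk-flow
complexes are disproportionately sensitive to vesicle-size changes.

**Strain anchors.** The double-mutant (emp24del lst1del) median volume,
31,493 nm³, is a measured anchor. The emp24del median volume is implied by
the reported 21% volume reduction of the double mutant relative to it
(31,493/0.79 ≈ 39,865 nm³). The WT median volume was never measured and
defaults to an ASSUMED 38,300 nm³; every WT-referenced percent change is
therefore model-assumption-dependent, and the pipeline logs a warning saying
so. With these defaults the model yields ≈ +16% available volume in
emp24del vs WT, ≈ −24% in the double mutant vs WT, and K increases of
≈ +20% (1 MDa complex) vs ≈ +3% (Cp) between the WT-like and emp24del-like
conditions — the ≥ 5× sensitivity ordering is robust to the WT assumption,
the exact magnitudes are not.

## Monte-Carlo oracles

Deliberately simple, seed-deterministic estimators verify the analytic
results by brute force; they are kept dumber than the code they check and
are never the production path.

- **Partition oracle.** Cargo centers uniform in the R_av sphere by
  rejection sampling in the bounding cube (acceptance π/6 — trivially
  auditable, no inverse-CDF); K̂ = fraction with |center| ≤ R_av − r_cargo,
  SE = √(K̂(1−K̂)/n).
- **Volume oracle.** Uniform samples in the mesh's bounding box classified
  by ray-crossing parity. The ray direction is drawn per point from the six
  signed coordinate axes (together with the random sample positions this
  makes edge/vertex grazing a measure-zero event); a point within a relative
  tolerance of a face counts as inside. Axis-aligned rays allow an x-sorted
  sweep confined to each triangle's 2D bounding box, so 10⁶ parity tests
  against a 5,120-triangle mesh take ~2 s on one CPU.
- **Parameter recovery.** Generate a population from a preset, measure it,
  and check that the anchored target lies inside the 95% bootstrap CI of the
  recovered median.

## Problem sizes and tolerances

Test and acceptance runs use 500-vesicle populations at 150 points each,
2,000 bootstrap resamples, 10⁵ samples per partition-oracle grid point and
10⁶ for mesh-volume oracles — sizes at which every check completes in
seconds while the Monte-Carlo standard errors are small enough to resolve
sub-percent discrepancies. Oracle agreement is asserted within 3 standard
errors; mesh volume of ≥ 2,562-vertex icospheres is within 1% of the
analytic value (the residual is discretization deficit of the inscribed
polyhedron, not numerical error); bootstrap CI coverage is required in
90–99% over 200 replicate populations. Degenerate inputs fail loudly:
non-positive radii/volumes, open meshes (boundary-edge count named),
fully occupied vesicles (deficit named), empty axes/mixes.

## Known limitations

- Real vesicle surfaces deviate from ellipsoids (necks, flattening against
  the ER, segmentation artefacts); passing recovery tests shows the pipeline
  measures what the generator produces, not that tracing bias in real
  tomograms is small.
- The partition model ignores crowding inside the available volume,
  electrostatics, hydration, and non-spherical cargo; K is an equilibrium
  dilute-limit quantity.
- The WT median volume anchor is an assumption (see above); conclusions that
  depend on its exact value are flagged in output.
- The bootstrap CI of the median undercovers slightly for very small
  populations (n ≲ 20); the defaults target n ≥ 100.
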