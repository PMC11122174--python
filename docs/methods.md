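# Methods

`orbitmorph` measures the bony orbit — an open skeletal cavity with thin,
often sub-resolution walls and no anterior bony border — on CT-like
attenuation volumes. Because no patient CTs ship with the package, every
stage is exercised on synthetic phantoms with closed-form ground truth;
this note records the models, the parameters that matter, and what the
phantom results do and do not say about clinical data.

## Phantom model

A phantom is a blind cavity of revolution (hemisphere, cone, or paraboloid
of depth `L` and aperture radius `R`) filled with soft tissue (+40 HU),
enclosed by a bone shell (+700 HU, default 1.5 mm thick), embedded in a
soft-tissue block and opening anteriorly through a planar aperture flush
with the block's anterior face; air (−1000 HU) lies in front. Ground truth
is analytic: e.g. a paraboloid has volume πR²L/2 and lateral area
πR/(6L²)·[(R²+4L²)^{3/2} − R³]. The reported truth area includes the
planar aperture cap; a separate field carries the lateral-only value
because whether a published surface area includes the artificial closures
is generally ambiguous — `mesh_area(include_closures=...)` exposes the
same choice.

**Wall porosity.** Real orbital walls are non-continuous in CT. We emulate
this by deleting a seeded random fraction of shell voxels. At 0.5 mm
voxels and 1.5 mm walls, a 5 % dropout rate is fully sealed by the default
gap bridging and is the study condition for cohort and validation
phantoms; ~10 % produces genuine perforations (caught by the leak guard),
and at ≥ 0.8 mm spacing the wall thins to a single voxel so any dropout
perforates — scaled-down tests therefore use intact walls. Because a
random gap pattern can occasionally stack dropouts into a real
perforation even at 5 %, validation phantoms pass a seal QC
(`make_sealed_phantom`): the soft-tissue component reachable from the
seed is compared against the closed-form cavity volume and the gap
pattern is redrawn deterministically until the wall holds, enforcing the
generator's full-wall-coverage contract. Porosity is
random voxel dropout, not anatomical fissures: it tests gap bridging, not
anatomy.

**Defects.** `lacrimal_channel` carves a bone-sheathed soft-tissue channel
(2.5 mm radius, wider than the bridging ball, so it stays open) into a
bone-enclosed pocket of nominally 0.6 mL; segmentation then includes
pocket + channel, and the truth records the exact constructed extra
volume. `wall_fracture` removes a ~100 mm² wall patch, opening the cavity
into the surrounding block.

## Segmentation

1. **Bone threshold** — Otsu's criterion over voxels above −200 HU
   (restricting away the air mode); the tool being emulated states only
   that the threshold is "optimized", so Otsu is our choice.
2. **Gap bridging** — morphological closing of the bone mask with a
   Euclidean ball (default radius 1.5 mm: seals 1–2-voxel dropouts at
   typical 0.5–0.7 mm resolution without closing real apertures),
   implemented as two distance transforms, which is exact under
   anisotropic spacing.
3. **Cavity growth** — one-voxel 6-connected front propagation from a
   small seed ball, restricted to soft-tissue voxels (HU above the air
   cutoff) outside the bridged bone. Growth stops at bone, at air (which
   is what terminates the anterior face in the phantom geometry), or on
   the leak guard.
4. **Leak guard** — on an intact bone-bounded cavity the per-iteration
   growth rises while the front expands freely, then declines essentially
   monotonically once it meets the walls (measured re-acceleration ≤ 1.006
   across the phantom suite). A breach re-expands the front: ≥ 2.4× the
   post-decline trough in fracture phantoms. The guard therefore arms once
   growth falls below 70 % of its running peak and aborts when it exceeds
   `leak_guard_factor` (default 2) times the trough. Limitation: a leak
   into a small pocket that fills *concurrently* with the cavity produces
   no re-acceleration and passes silently — which is precisely how a
   thickened lacrimal duct inflates a measured volume in practice; such
   errors surface downstream in the bilateral asymmetry screen rather than
   in segmentation.
5. **Concavity refinement** — ball closing of the wall also seals sharp
   cavity concavities the ball cannot enter (a conical apex loses ~2 mm of
   depth). The refine step returns the surface to the true bone by filling
   sealed soft-tissue pockets that touch the cavity and are enclosed
   entirely by bone + cavity; through-wall gap plugs touch open soft
   tissue or air and fail the enclosure test, so the seal of the wall is
   preserved. The raw grown mask (before refinement) never intersects the
   bridged bone mask — that invariant is what the tests assert voxelwise.
6. **Closures** — aperture faces (cavity boundary not adjacent to bone)
   are grouped into connected components and capped by their own voxel
   faces; each cap carries an area-weighted centroid ("mid-point") and a
   least-squares plane normal. The largest cap is the anterior closure;
   the rest are posterior caps (an area cutoff, default 150 mm², flags
   unexpectedly large secondary apertures with a warning). Whether a
   commercial tool caps posterior gaps at the bone plane or includes canal
   volume is unknowable from outside; we cap all secondary apertures and
   expose the cutoff.

Everything is deterministic — identical volume and configuration give
bit-identical masks across runs and processes. That, not statistical
agreement, is why the repeated-measurement ICCs come out exactly 1.0.

## Morphometry

Cavity voxels are decomposed into 6 tetrahedra each (fan around the voxel
diagonal, derived programmatically at import so boundary triangles match
the decomposition exactly). Volume is Σ|det|/6, algebraically equal to
voxel count × voxel volume, and equal to the divergence-theorem surface
integral of the labelled boundary to 10⁻⁹ mL (a dual-route test).

Surface area is measured on a marching-cubes isosurface of the
Gaussian-smoothed (σ = 1 voxel) occupancy field: the raw voxel boundary
overestimates a smooth surface by ~50 % (staircase), and published
cm²-scale orbital areas imply a smooth surface. Smoothed areas land within
a few percent of the closed forms; the planar closure-cap area is
subtracted when caps are excluded.

Depth (axial orbital length) is the distance from the anterior cap's
area-weighted centroid to the farthest mesh vertex, with exact ties broken
lexicographically. For a hemisphere this farthest point is degenerate (rim
and pole are equidistant), so the depth *value* is still correct but the
axis direction is arbitrary — real orbits and the other phantom families
are elongated (`L > R`) and have a unique apex.

The volume profile projects tetrahedron centroids onto the depth axis,
bins them into `n_bins = 10` equal pieces (half-open, last bin closed),
excludes volume anterior to the cap mid-point, and reports bins ordered
from the apex toward the rim, so the cumulative profile is volume as a
function of relative distance from the apex. Conservation
(Σ profile + excluded = volume) holds to 10⁻⁹ mL by construction. For a
cone the cumulative profile follows (k/10)³ once the voxel-scale
truncation of the measured axis at the apex is accounted for; tests check
the plain cubic law at 0.02 and the truncation-corrected law at 0.005.

## Synthetic cohorts

The generator's defaults are the published reference summary for 174
adults (91 men, 83 women): per-gender side-averaged means/SDs of depth
(39.79/37.34 mm), volume (28.99/25.44 mL) and area (3875/3491 mm²), the
published R² couplings, age 38.5 ± 13.5 clipped to 18–74, and a one-sided
defect probability of 12/186.

* Depth is gender-normal; volume = α_g + β·depth + ε with a **shared**
  slope β (the reference interaction model found no gender-specific
  slope). A shared slope cannot satisfy both genders' V×L R² targets and
  their volume SDs simultaneously; we set β to the mean of the per-gender
  implied slopes and the noise to hit the volume SDs, giving realized V×L
  R² ≈ 0.62–0.64. Area | volume is fitted per gender and hits its A×V R²
  targets exactly.
* Sides are the subject value ± half a left-right difference drawn with
  SD 0.07 mL for volume (0.10 mm depth, 10 mm² area). The reference study
  does not report this SD (all retained subjects were within 0.2 mL);
  0.07 mL is interpreted as the SD of the *difference*, keeping natural
  flags rare (~0.4 %) so the screen's yield is defect-driven, and is
  configurable.
* Defects add 0.3–1.5 mL to one side, with kinds in the observed 5:3:4
  ratio (lacrimal : fracture : generalized asymmetry); only the first two
  carry an image-level phantom defect.

What passing cohort tests show: the analysis battery recovers the
qualitative reference signature (gender significant everywhere, sides
indistinguishable, larger-vs-smaller paired-significant but unpaired not,
depth the only significant model term) in ~98 of 100 seeded cohorts. What
they do not show: anything about scanner noise, Hounsfield calibration,
real anatomical variation, or the absolute accuracy of segmentation on
clinical images — the phantom walls, materials and shapes are idealized.

## Statistics

Unpaired comparisons use Welch's t (the robust default; the reference
p-value gaps are insensitive to the choice), paired comparisons the paired
t within subject; larger-vs-smaller takes the per-subject max/min over
sides and, per the reference's printed design, also runs the unpaired
version treating orbits as independent. Normality is Shapiro–Wilk. The
interaction model is OLS `volume ~ 1 + gender + depth + gender:depth` with
male = 1. No multiple-testing correction is applied, matching the
reference analysis. The ICC is the two-way random-effects,
absolute-agreement, single-measurement form by direct ANOVA decomposition
(a consistency form is available); it is cross-checked against an
independent implementation to 10⁻¹⁰. Zero between-subject variance returns
0.0 with a warning. The derived ratios are the male-female volume
difference as a percent of the female mean (side-averaged) and mean volume
(mL) over mean area (cm²) per gender × side plus their average.

The validation harness replays the repeated-measurement protocol — by
default 10 bilateral cases × 6 simulated operators × 2 runs = 240 full
pipeline executions at 0.5 mm voxels — and computes the intra-operator ICC
(rows case × side × operator, columns runs) and inter-operator ICC (rows
case × side, columns operator run-means). An optional per-operator volume
jitter degrades only the inter-operator ICC, confirming the two indices
separate the intended variance components.

## Numerical choices and scale

Lengths are mm, volumes mL (= cm³), areas mm²; physical coordinates are
voxel centers, `origin + (index + 0.5)·spacing`; voxel indices are
0-based. Problem sizes: unit tests run on 10–15 mm phantoms; recovery and
profile properties on 20–40 mm phantoms at 0.5 mm spacing (grids of ~1M
voxels, 1–3 s per orbit); the refinement check adds 1.0 and 0.25 mm grids,
asserting error decrease down to a 5·10⁻⁴ relative noise floor below which
voxel-sampling fluctuation dominates. The full ICC protocol (240 runs)
takes about 6–7 minutes on one CPU. Monte-Carlo statistical tests use
fixed seed lists and are fully reproducible.

## Known limitations

* Orbit localization is out of scope: a seed voxel inside the cavity must
  be supplied (phantom truth provides it; the CLI takes `--seed-voxel`).
* The leak guard is a heuristic on front dynamics; concurrent-fill leaks
  pass (by design they are the asymmetry screen's job).
* Depth of a porous-walled phantom legitimately reaches into wall divots
  (bone is genuinely absent there), so depth recovery is specified for
  intact walls.
* The generator reproduces first and second moments and the stated
  couplings, not higher-order shape of the reference distributions.
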