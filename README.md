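# orbitmorph

Automated morphometry of the bony orbit on CT-like volumes: cavity
segmentation bounded by thin (often non-continuous) bone, tetrahedral
measurement of volume, surface area and axial depth, a normalized
depth–volume profile, bilateral asymmetry screening, and the cohort
statistics used to characterize orbital dimensions in adults.

It is written for researchers in craniofacial imaging who need a fully
reproducible, scriptable stand-in for commercial orbital-analysis tools —
and, because patient CTs are rarely shareable, it ships a synthetic
phantom generator with closed-form ground truth so every stage of the
pipeline is testable end to end.

## The measurements

Given an attenuation volume and a seed voxel inside the orbit, the
pipeline thresholds bone (Otsu above the air mode), seals sub-resolution
wall gaps by morphological closing with a physical ball radius, grows the
cavity by front propagation until it meets the bone (with a leak guard
that aborts when the front re-accelerates through a wall breach), and caps
the remaining apertures with planar closures. On the resulting tetrahedral
mesh it reports:

* **V** — cavity volume, Σ |det|/6 over tetrahedra (mL);
* **A** — boundary surface area on a lightly smoothed isosurface (mm²);
* **L** — axial orbital length: distance from the anterior closure's
  mid-point to the posterior-most point of the cavity (mm);
* the **volume profile**: V binned over L in ten equal pieces from the
  apex toward the rim, excluding volume anterior to the closure mid-point.

Cohort analysis includes the 0.2 mL left–right asymmetry screen,
Shapiro–Wilk normality, Welch/paired t comparisons (gender, side,
larger-vs-smaller orbit), the interaction model
`Volume ~ 1 + Gender + Depth + Gender:Depth`, R² correlations among V, A
and L, ANOVA-based intraclass correlation coefficients, and the derived
ratios (male–female volume difference ≈ 14 %, V/A ≈ 0.75 mL/cm²).

## Worked example

```python
import numpy as np
from orbitmorph import PhantomSpec, make_phantom, run_orbit_pipeline

spec = PhantomSpec("paraboloid", depth_mm=38.0, aperture_radius_mm=21.0,
                   wall_gap_fraction=0.05, rng_seed=3)
volume, truth = make_phantom(spec)
metrics = run_orbit_pipeline(volume, truth.interior_voxel(volume))
print(f"truth:    V={truth.volume_ml:.3f} mL  A={truth.area_mm2:.1f} mm^2  L={truth.depth_mm:.1f} mm")
print(f"measured: V={metrics.volume_ml:.3f} mL  A={metrics.area_mm2:.1f} mm^2  L={metrics.depth_mm:.2f} mm")
print("profile (apex->rim, mL):", np.round(metrics.profile_ml, 2))
print(f"excluded anterior: {metrics.excluded_anterior_ml:.3f} mL")
```

prints

```
truth:    V=26.323 mL  A=5047.6 mm^2  L=38.0 mm
measured: V=26.411 mL  A=4977.3 mm^2  L=38.53 mm
profile (apex->rim, mL): [0.2  0.74 1.28 1.82 2.37 2.91 3.46 4.   4.54 4.84]
excluded anterior: 0.242 mL
```

The phantom is a paraboloid orbit (38 mm deep, 21 mm aperture radius) with
5 % of its 1.5 mm bone wall randomly dropped to mimic the non-continuous
thin walls of real orbits. The measured volume lands within 0.4 % of the
closed form, area within 1.4 %, depth within ~one voxel, and the profile
increases from apex to rim — the largest volume gain per unit depth sits
in the anterior bins, as in real orbits.

The same stages are available from the shell:

```bash
orbitmorph pipeline out/ --seed 1        # cohort -> screen -> statistics
orbitmorph measure scan.nii.gz --seed-voxel 40 80 80 --out-json orbit.json
orbitmorph validate --out-json icc.json  # 10x6x2 repeated-measurement ICC
```

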