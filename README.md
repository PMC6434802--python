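# aneumorph

Morphometric rupture-risk parameters of intracranial aneurysms, and the
uncertainty those parameters inherit from segmentation and surface
reconstruction.

Unruptured intracranial aneurysms are common incidental findings, and
clinicians weigh treatment risk against rupture risk. Many geometric
parameters of the aneurysm sac — height, volume, aspect ratio,
nonsphericity, surface curvature statistics — have been proposed as
rupture-risk predictors. All of them are computed from a triangulated
surface that depends on which segmentation pipeline produced it. When
several groups reconstruct the *same* aneurysm from the same scan, each
parameter scatters; a parameter whose scatter is comparable to its
between-patient variation is useless in a prediction model, however
plausible its biomechanics. `aneumorph` provides both halves of that
analysis:

* **Morphometry** — given an aneurysm dome (an open triangle mesh in mm
  whose single boundary loop is the neck curve, plus optionally the
  parent-vessel diameter), compute 40 standard parameters: 12
  dimensional size parameters (`H`, `L_max`, `H_max`, `D_max`, `H_b`,
  areas `A`, `A_CH`, `A_MBS`, `A_closed`, volumes `V`, `V_CH`,
  `V_MBS`), 6 neck parameters (`D_neck,min/max`, `P_neck`,
  `D_neck,equiv`, `A_neck`, `A_neck,elliptical`), 12 dimensionless
  shape indices (`SR`, `AR`, `eAR`, `BF`, `BL`, `NSI`, `IPR`, `AVSV`,
  `AASA`, `UI`, `CR`, `EI`) and 10 curvature statistics (`MAA`,
  `absMAA`, `MSD`, `HMC`, `MLN`, `GAA`, `absGAA`, `GSD`, `HGC`, `GLN`).
* **Uncertainty quantification** — given a cohort table of those
  parameters over aneurysms × reconstructions ("groups"), compute per
  aneurysm the median and the middle 68.3 % range
  (P84.13 − P15.87, the ±1 SD band for normal data), the relative
  uncertainty `100 · range / median` in %, absolute relative
  deviations for boxplots, and the supporting statistics (Kendall
  τ-b, Wilcoxon signed-rank, Shapiro–Wilk, OLS of range on median).
* **Synthetic cohorts** — analytic spherical-cap and ellipsoid-cap
  domes (every vertex exactly on the generating quadric, closed-form
  truth records) plus a seeded perturbation model of inter-group
  variability: global over/under-sizing, surface noise along normals,
  Taubin-style smoothing, and neck-plane tilt/offset with re-cutting.

Key definitions, in the field's usual notation (`V` and `A_closed` are
volume and area of the neck-closed sac, `V_CH`/`A_CH` of its convex
hull, `r_MBS` the minimal-bounding-sphere radius):

```
IPR = A_closed / V^(2/3)          NSI = 1 − (18π)^(1/3) / IPR
CR  = V / V_CH                    UI  = 1 − CR
EI  = 1 − (18π)^(1/3) V_CH^(2/3) / A_CH
AR  = H / D_neck,max              BF  = D_max / D_neck,max
HMC = 100 (⟨|H_mean|⟩ · r_MBS − 1)   [%; analogously HGC with r_MBS²]
MLN = ‖H_mean‖_L2 / 4π            GLN = sqrt(A · ∮K² dA) / 4π
```

Mean curvature comes from the cotangent Laplace–Beltrami operator with
mixed Voronoi vertex areas, Gaussian curvature from the angle deficit;
both are evaluated on interior vertices only (the neck crease has no
well-defined curvature).

## Worked example

Measure a synthetic aneurysm shaped like a spherical cap (base diameter
5 mm, height 4 mm, 0.2 mm triangulation — sphere radius R = 2.78125 mm),
with a 3 mm parent vessel:

```python
from aneumorph import (AneurysmDome, CapSpec, compute_parameters,
                       make_spherical_cap)

dome, truth = make_spherical_cap(CapSpec(diameter=5, height=4, edge_length=0.2))
dome = AneurysmDome(surface=dome.surface, parent_vessel_diameter=3.0,
                    aneurysm_id="phantom")
record = compute_parameters(dome)
for name in ("H", "L_max", "D_max", "A", "V", "SR", "AR", "NSI", "IPR", "MLN"):
    print(f"{name:6s} {record[name]:8.4f}")
```

prints

```
H        4.0000
L_max    5.5618
D_max    5.5600
A       69.8221
V       72.6254
SR       1.3333
AR       0.8002
NSI      0.2529
IPR      5.1379
MLN      0.2391
```

`H` is exact (the apex is a mesh vertex); `L_max` and `D_max` approach
the sphere diameter 2R = 5.5625 mm because this cap is taller than a
hemisphere and contains its equator; the measured area and volume are
within 0.11 % and 0.21 % of the closed forms 2πRh = 69.90 mm² and
πh²(R − h/3) = 72.78 mm³ — mesh discretization error, not measurement
error. `AR` = 4/5 is height over maximum neck diameter, and `NSI`,
`IPR`, `MLN` are the dimensionless irregularity indices (a closed
hemisphere would give NSI = 1/3 exactly).

The same pipeline runs from the shell:

```sh
aneumorph synth   --spec cohort_spec.json --outdir fixtures/
aneumorph compute --manifest fixtures/manifest.json --out params.csv
aneumorph uq      --table params.csv --outdir tables/ --percentile-method spss
```

`uq` writes four per-group tables (size, neck, non-dimensional,
curvature) with the per-parameter median [IQR], relative uncertainty
median [IQR] and τ between medians and uncertainties, plus boxplot data
of the absolute relative deviations.

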