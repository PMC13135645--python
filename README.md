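# avflow

Geometry and haemodynamics of arteriovenous fistulas (AVFs), the surgical
artery-to-vein connections created for haemodialysis access.  Up to 60% of
newly created AVFs fail to mature, and both the local anatomy (vessel
diameters, curvature, anastomosis angle) and the wall shear stress (WSS)
environment it creates are implicated.  `avflow` provides a tested,
reusable pipeline for studying these relationships:

* **Synthetic AVF lumens** — parameterised end-to-side fistula surface
  meshes (feeding artery, draining vein, distal artery) with controllable
  diameters, centreline curvatures and anastomosis angle, built as an
  implicit signed-distance union triangulated by marching cubes, so every
  downstream stage is testable without patient imaging.
* **Pulsatile wall shear** — the rigid-tube axisymmetric (Womersley)
  solution per flow harmonic, scaled so each harmonic's flow matches the
  prescribed waveform; the steady component is the Poiseuille value
  τ₀ = 4μQ₀/(πR³).
* **Anatomical characterisation** — cross-section-marching centreline
  extraction, equivalent-circle diameters D = 2√(A/π), local-regression
  curvature κ = |r′×r″|/|r′|³, the anastomosis angle from directed line
  fits at the junction, and 1 cm arclength segmentation with the
  anastomosis kept as its own patch.
* **WSS metric suite** — per-face TAWSS = (1/T)∫‖τ_w‖dt,
  OSI = ½(1 − ‖∫τ_w dt‖/∫‖τ_w‖dt) ∈ [0, 0.5],
  transWSS = (1/T)∫|τ_w·(n×p)|dt, the surface-gradient magnitude WSSG,
  and localised normalised helicity LNH = v·ω/(‖v‖‖ω‖), aggregated per
  1 cm segment by area-weighted means; plus a lumped Poiseuille
  (R = 8μL/πR⁴) pressure network that reproduces the
  P_feeding > P_distal ≈ P_anastomosis > P_vein ordering and flags distal
  flow reversal (steal).
* **Cohort statistics** — a packaged 17-fistula cohort table (anatomy,
  venous outflow, maturation outcome), group summaries with the
  population-SD convention, rank-based group comparisons, and
  Mann–Whitney ROC AUC (with exhaustive pair counting,
  AUC = (concordant + ½·tied)/(n₊n₋)) for predicting high venous outflow
  (⩾ 1000 ml/min), including a combined logistic score over several
  predictors.

## Worked example

Cohort analysis of the packaged table:

```python
from avflow import load_table2_fixture, dichotomize_flow, group_summary, mw_auc

cohort = dichotomize_flow(load_table2_fixture())   # High iff >= 1000 ml/min
gs = group_summary(cohort, "outcome").set_index(["group", "variable"])
print(gs.loc[("S", "fa_diameter_mm"), ["mean", "sd"]])
r = mw_auc(cohort.anastomosis_angle_deg, cohort.outflow_category)
print(f"angle AUC {r.auc:.4f} ({r.n_pos} high / {r.n_neg} low)")
```

prints

```
mean    4.710308
sd      1.446207
Name: (S, fa_diameter_mm), dtype: float64
angle AUC 0.6667 (8 high / 9 low)
```

i.e. successful fistulas have a mean feeding-artery diameter of 4.71 mm
(population SD 1.45 mm), and the anastomosis angle separates high- from
low-outflow fistulas with a concordance of 0.6667 (48 of 72 pairs).  The
same analysis from the shell:

```sh
avf stats --out stats_run
```

```
                                  variable  orientation      auc  n_pos  n_neg  ties
                            fa_diameter_mm            1 0.902778      8      9     0
                              fa_curvature           -1 0.812500      8      9     1
                            dv_diameter_mm            1 0.833333      8      9     0
                              dv_curvature           -1 0.701389      8      9     5
                     anastomosis_angle_deg            1 0.666667      8      9     0
fa_curvature+fa_diameter_mm+dv_diameter_mm            1 0.902778      8      9     0
```

Orientation −1 means smaller values predict high outflow (straighter
feeding arteries carry more flow).  A full synthetic run — build a lumen,
generate its pulsatile wall-shear field, recover the anatomy from the mesh
and compute segment-wise WSS metrics — is one call:

```sh
avf metrics --out full_run          # synth + geometry + metrics
avf report --run full_run/manifest.json
```

Geometry recovery on a synthetic fistula:

```python
from avflow import (AVFDesignParams, build_end_to_side_avf,
                    extract_limb_centrelines, summarise_anatomy)

avf = build_end_to_side_avf(AVFDesignParams(anastomosis_angle=62.0))
seeds = {lab: cl.point_at(cl.length - 2.0) for lab, cl in avf.centrelines.items()}
rec = extract_limb_centrelines(avf.mesh, avf.anastomosis_faces, seeds, avf.junction)
s = summarise_anatomy(avf.mesh, rec, avf.anastomosis_faces)
print(f"{s.feeding_artery_diameter:.2f} mm, {s.anastomosis_angle:.1f} deg")
# -> 4.68 mm, 62.0 deg   (designed: 4.70 mm, 62.0 deg)
```

## Layout

| module | contents |
|---|---|
| `avflow.synthetic` | AVF design parameters, tube sweep and implicit-union builders, cohort generator |
| `avflow.womersley` | flow waveforms, pulsatile rigid-tube wall shear |
| `avflow.geometry` | centrelines, curvature, diameters, segmentation, anatomical summary |
| `avflow.metrics` | TAWSS / OSI / transWSS / WSSG / LNH, segment aggregation, lumped pressure network |
| `avflow.stats` | packaged cohort, group summaries, Mann–Whitney and combined ROC |
| `avflow.fields`, `avflow.pipeline`, `avflow.cli`, `avflow.plots` | formats, orchestration, `avf` command line, figures |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and numerical choices.
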