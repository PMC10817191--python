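# aerolung

Respiratory geometry from plain chest radiographs, and where inhaled drug
lands in it.

Volumetric CT gives patient-specific airway geometry for aerosol
deposition modelling, but most patients only ever receive a chest X-ray.
`aerolung` implements the image-processing side of a framework that closes
that gap:

* a **statistical shape-and-appearance model (SSAM)**: PCA over
  corresponded lung/airway landmarks augmented with projected gray values,
  `z ≈ z̄ + Σ_m Φ_m (b_m σ_m)`, built from a training cohort and able to
  generate new anatomies from a handful of mode weights;
* **2D→3D reconstruction**: digitally reconstructed radiographs (DRRs),
  Canny edge maps, and a gradient-free fit of mode weights, scale and
  translation minimising
  `L = C_fit·L_fit + C_prior·L_prior + C_g·L_g + C_AS·L_AS`
  (silhouette-to-outline distance, Mahalanobis shape prior, gray-value
  match, anatomical-shadow contrast), plus Gaussian-kernel template-mesh
  morphing of the result into a surface;
* **volume-filling airway generation**: the imaged central airways are
  extended to a full conducting tree by iteratively clustering seed points
  (grid spacing `Δ = (V_lung/N_T)^{1/3}`) around growing branch tips,
  with geometric diameter assignment and per-generation morphometry;
* a **lumped-parameter (0D) outlet model**: per-outlet resistance and
  compliance distributed from global adult values
  (`R_global = 7×10⁻³ cmH₂O·s/mL`, `C_global = 59 mL/cmH₂O`) so they
  recombine exactly, tidal and constant-flow breathing profiles, and a
  quasi-static network simulator with backflow clamps;
* **deposition metrics**: Stokes relaxation times, a minimal Lagrangian
  drag+gravity tracker with wall sticking, per-region deposition
  fractions, and the deposition enhancement factor
  `DEF = (N_patch/A_conc)/(N_total/A_tot)` on 1 mm wall patches;
* the **segmentation training losses** (soft Dice + focal, γ = 5) used by
  the CT route of the framework, as standalone functions;
* **seeded phantom generators** (lung labelmaps, landmark populations
  with known modes, analytic radiographs, deposition point clouds) so the
  whole pipeline is testable without clinical data.

Everything operates on standard formats: NIfTI / MetaImage volumes, STL
meshes, CSV landmark tables, JSON airway trees.

## Worked example

Build a shape model from a synthetic population with two known variation
modes, then reconstruct ten unseen phantoms from their frontal
radiographs:

```python
import numpy as np
from aerolung.studies import ssam_recovery_study, volume_recovery_study

res = ssam_recovery_study(n_samples=200, seed=0)
print(f"retained modes : {res['n_modes_retained']}")
print(f"leading-mode alignment |cos| : {res['leading_mode_cos']:.4f}")

study = volume_recovery_study(n_cases=10, seed=0, budget=500)
print(f"median lung-volume error : {study.median_error_pct:.2f}%")
print(f"per-case errors (%) : {np.round(study.volume_errors_pct, 2)}")
```

prints

```
retained modes : 2
leading-mode alignment |cos| : 0.9996
median lung-volume error : 0.52%
per-case errors (%) : [15.9   0.59  6.25  0.38  0.24  0.16  1.96  0.08  0.59  0.46]
```

The model keeps exactly the two modes that generated the population and
recovers the leading one almost perfectly. Fitting the model to each
phantom's radiograph recovers total lung volume with sub-percent median
error; the one 16% case is the characteristic outlier mode of
outline-based fitting (an ambiguous edge configuration), the same failure
class seen on clinical radiographs.

The same stages are exposed as a CLI for shell use:

```bash
aerolung make-phantom --out work/ --population 20
aerolung build-ssam --landmarks work/landmarks --variance 0.9 --out model.npz
aerolung grow-airways --mask work/labelmap.nii.gz --tree-in work/tree.json \
        --out tree.json --nt 1000
aerolung simulate-0d --network net.json --profile tidal --vt 600 --tb 4 \
        --dt 0.001 --out series.csv
aerolung def-map --mesh m.stl --particles p.csv --radius 1.0 --out def.csv
```

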