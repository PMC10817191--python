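# Methods

`aerolung` implements a pipeline for producing patient-specific 3D
respiratory geometry from 2D chest radiographs and deriving
deposition-relevant quantities from it. This note records the models, the
numerical choices, and what the synthetic studies do and do not
demonstrate.

## Shape-and-appearance model

Each training subject is a corresponded landmark set: `N_L` 3D points on
the lung (and central airway) surfaces, each carrying the radiograph gray
value sampled at its projected position for each of `N_XR` projections
(frontal, optionally lateral). The per-subject state vector has length
`(3 + N_XR)·N_L`; this package stores it block-wise (all coordinates, then
all gray values), which spans the same space as the interleaved
per-landmark layout.

Before modelling, each sample is aligned: landmark coordinates are
translated to zero mean and divided by the standard deviation over all
`3·N_L` flattened entries (population convention), and gray values are
normalised to zero mean and unit SD per projection within the sample. The
removed similarity transform is kept so fitted shapes can be mapped back
to millimetres.

PCA of the aligned states (via SVD of the centered data matrix — the
`(3+N_XR)·N_L`-dimensional covariance is never formed) gives the linear
generative model

    z ≈ z̄ + Σ_m Φ_m (b_m w_m),   m = 1..N_m,

with orthonormal modes `Φ_m` and per-mode variances `σ_m²`. `N_m` is the
smallest count reaching the 90% explained-variance target. The mode weight
`w_m` defaults to `σ_m` so that `b` is in standard-deviation units and the
fitting bound `|b_m| ≤ 3` spans ±3 SD of the training population; a
`mode_weighting="variance"` switch (`w_m = σ_m²`) reproduces the
literal published weighting, which is ambiguous in print.

Model quality is assessed by the reconstruction error (project + rebuild a
training sample with `k` modes) and the leave-one-out generalisation error
(rebuild the model without the sample first). Both are mean landmark
distances as a percentage of the sample's bounding-box diagonal. The
diagonal is used because the reference norm for "bounding-box size" is
otherwise unspecified. Leave-one-out is run once per sample; no outer
repetition loop is applied.

## Radiograph fitting

A radiograph (synthetic DRR or loaded image) is reduced to a lung-outline
edge-point set: downsample ×4 by block averaging, global histogram
equalisation, Canny with a 2-pixel Gaussian kernel, and mapping of edge
pixels back to millimetres at coarse-pixel centres. This pipeline
suppresses rib-cage-scale clutter at the cost of edge localisation no
better than ~1.5 coarse pixels.

The fit minimises

    L = C_fit·L_fit + C_prior·L_prior + C_g·L_g + C_AS·L_AS

over the mode weights `b` (init 0, bounds ±3), an isotropic scale and a 3D
translation. Defaults `C_fit = 0.795`, `C_g = 0.687`, `C_prior = 4.4e-4`,
`C_AS = 0.2` are the published optimum for chest radiographs and are not
re-tuned here.

* `L_fit = 1 − (1/N_SL) Σ exp(−d_i / C_dist)` with `C_dist = 5` mm, where
  `d_i` is the distance from each projected silhouette landmark to its
  nearest edge point. Silhouette landmarks are those whose nearest
  template-mesh vertex is shared by faces whose normals straddle the
  projection axis; airway-tagged landmarks are excluded (their outline is
  unreliable on a radiograph). The silhouette set is computed once from
  the template mesh at the mean shape and held fixed during optimisation —
  recomputing it per candidate would dominate the runtime for a
  second-order effect.
* `L_prior` is the squared Mahalanobis distance from the training mean
  under the training covariance, divided by `N_L`. It is evaluated in mode
  space (`Σ b_m²` with SD weighting), which is exact on the retained
  subspace; a dense pseudo-inverse evaluation exists for cross-checks but
  is rank-deficient for small cohorts.
* `L_g` is the mean absolute difference between modelled and sampled gray
  values. Both vectors are standardised before comparison — the model
  stores per-sample-normalised grays, so comparing raw image samples
  against them would mix scales.
* `L_AS` (anatomical shadow) compares mean gray inside circular ROIs
  (radius 14 px) placed ±20 px along the outward 2D border normal of each
  airway silhouette landmark: `(ḡ_in − ḡ_out)/ḡ_out`. As printed the term
  is signed; a `shadow_abs` flag takes the magnitude instead, since for
  structures darker than their surroundings minimising the signed form
  maximises contrast.

Optimisation is gradient-free: differential evolution with an absolute
population of 16, box bounds, a fixed seed, and a budget of 500 loss
evaluations, of which the last 30% drive a Nelder–Mead simplex refinement
of the best member (clipped to the same bounds). The loss trace reported
is the running minimum. Pose (scale factor 0.85–1.15 around the mean
training scale, translation ±15 mm) is optimised jointly with `b`.

Fitted landmarks are converted to a surface by morphing a template mesh:
solve `K w = x_new − x_template` on the template landmarks with the
Gaussian kernel `k(a,b) = exp(−‖a−b‖²/(2σ²))`, `σ = 0.3` in template
units, then displace every vertex by the kernel-weighted sum. The
published kernel formula lacks the minus sign and the square (it would
grow with distance); the Gaussian is implemented as the text names it,
with the literal exponential variant switchable for sensitivity checks.
Duplicate landmarks trigger a `1e-10` ridge with a warning.

## Distal airway generation

Seed points fill the lung mask on a cubic grid of spacing
`Δ = (V_lung/N_T)^(1/3)`, `N_T = 30,000` for a full conducting tree
(tests and the acceptance study use `N_T ≈ 10³` so the run fits on one
CPU in seconds; the algorithm is scale-free in `N_T`). Growth iterates:
assign seeds to the nearest growing branch end (ties to the lowest branch
id); split each cluster by the plane through its centroid containing the
parent direction (normal = the centroid-offset component perpendicular to
the parent direction; a degenerate on-axis centroid falls back to any
perpendicular); grow a child 40% of the way to each sub-cluster centroid.
Single-seed clusters and candidates shorter than 2 mm close as terminal
bifurcations and delete their nearest seed.

Two deviations from the bare printed loop were needed for well-defined
termination: a single-seed cluster grows one terminal child toward its
seed (rather than closing the parent in place), and if seeds survive when
no branch can grow — possible because a closing branch deletes only its
nearest seed — each leftover seed receives one terminal child from the
nearest branch end under the same 40% rule. Both preserve the
one-terminal-per-seed accounting; an iteration guard of 4× the seed count
bounds the loop. Branches are not constrained to the mask (no
wall-avoidance rule is defined); out-of-mask nodes can be counted post
hoc.

Diameters follow `d = d₀·r^generation` with `d₀ = 16` mm (adult trachea)
and `r = 2^(−1/3) ≈ 0.794`, the flow-preserving reduction that halves
total cross-section every two generations. The distal-diameter model this
stands in for is configurable via `r`. Morphometry tables report
per-generation mean and SD of diameter normalised by the generation-0
mean. `tube_surface` builds capped frustum tubes for visualisation and
deposition fixtures, not CFD meshing.

## Lumped-parameter (0D) outlet model

Units are fixed: cmH₂O, mL, s, mm². Global adult parameters
`R_global = 7×10⁻³ cmH₂O·s/mL`, `C_global = 59 mL/cmH₂O`; `p_atm = 0`
(incompressible flow). Driving pressure `p_d = R·Q + V/C` is positive
during inhalation as printed; the standalone solver uses pleural pressure
`−p_d`, so a single outlet with matched R and C sits exactly at p = 0.

Per-outlet values distribute by outlet area within each lung and the
lung's static volume fraction α:

    C_i = (A_i/A_L)·α_L·C_global,   R_i = (A_L/(A_i·α_L))·R_global.

This grouping (the printed equation's grouping is typographically
ambiguous) is the unique one for which ΣC_i = C_global and the parallel
combination of R_i equals R_global for every network; it also preserves
the RC time constant at every outlet, which is why the quasi-static solver
splits delivered volume exactly by α.

Breathing profiles: tidal `V(t) = −½[V_T cos(2πt/T_B) − V_T]` and
constant flow `V(t) = V_T·t/T_inhale` with `T_inhale = T_B/2` (the
breath-actuated nebuliser setting, 18 L/min over 2 s). The quasi-static
solver enforces a common junction pressure and exact flux conservation at
every step, advancing volumes by forward Euler; the backflow clamps (max
outlet pressure 0, min outlet flux 0) follow the published stabilisation.
This solver is a desk-scale surrogate for a 3D solver's flux
distribution, not a CFD replacement.

## Particles and deposition

`τ_p = ρ_p d_p²/(18 μ)` with unit-density droplets (1000 kg/m³) and air
viscosity 1.9×10⁻⁵ Pa·s — the standard pair consistent with both printed
timescales (28 µs at 3.1 µm; 108 µs at 6.05 µm, our Stokes value 107.0 µs).
No Cunningham slip correction by default (none is given); a flag adds it.

The Lagrangian tracker integrates `dv/dt = (u−v)/τ_p + g` with symplectic
Euler and a `dt ≤ τ_p/5` stability guard; first wall crossing (vectorised
Möller–Trumbore segment–triangle test) sticks the particle. It is a
verification tool for the drag/gravity physics, not a flow solver.

Deposition fraction divides per-region deposited counts by all released
particles. The deposition enhancement factor per wall face is

    DEF = (N_patch/A_conc) / (N_total/A_tot),  A_conc = π·(1 mm)²,

with patch membership by Euclidean distance to the face centre (as
defined, not geodesic). A ground-truth denominator record can normalise
DEF maps from different reconstructions onto one scale. Because 1 mm
patches overlap and under-cover a curved triangulation, the face-mean DEF
of a uniform deposit is only ≈1 (within 10% on a fine sphere), not
exactly 1.

## Segmentation losses

Soft Dice is implemented with voxel sums inside the per-class ratio (the
printed per-voxel ratio is 0/0 on true negatives; that literal form is
available behind `per_voxel=True`), smoothed by ε = 10⁻⁷ — below every
tolerance used. Focal loss `−(1/CN) Σ α g (1−p)^γ log p` uses γ = 5,
α = 1; probabilities are clipped to [10⁻⁷, 1−10⁻⁷]. The combined training
loss is their sum. For single-channel pairs the channel is a foreground
probability and the sum-to-one check is skipped.

## Synthetic study conditions

The phantom emulates the structure the method needs, not anatomy in
detail:

* **Geometry.** Two superellipsoidal lungs (half-axes 60×40×90 mm,
  exponents 4/6/4 in x/y/z, 20 mm mediastinal gap) inside a soft-tissue
  torso with a tracheal air column. The raised exponents make the lateral
  and basal lung boundaries hug the projection direction, as real lungs
  hug the chest wall and diaphragm — without this, the projected boundary
  is a soft ramp that the fixed edge-map pipeline localises with a
  centimetre-scale inward bias. Subjects vary by isotropic size `u`
  (SD 6%) and cranio-caudal elongation `v` (SD 8%); 144 corresponded
  landmarks per subject (Fibonacci coverage plus two dedicated
  silhouette rings per lung).
* **Radiographs** are exact line integrals of the attenuation (closed-form
  chord lengths: no voxelisation noise) at 0.7 mm pixels with 1.5 mm
  Gaussian detector blur. The blur matters: without it, gray values
  sampled at boundary landmarks alias at sub-pixel scale between subjects
  and the PCA fills up with noise modes. The voxel-summation DRR path is
  exercised separately on labelmap phantoms.
* **Training cohort**: 38 subjects (the size of the clinical training set
  the framework targets), gray values sampled from each subject's own
  radiograph(s).
* **Recovery study**: 10 unseen subjects per run; fitted landmark sets are
  compared by convex-hull lung volume against the ground-truth landmark
  hull (identical landmark topology on both sides, so hull bias cancels).
* **Failure-mode study**: the lateral lung outline is obscured over the
  central 80% of the lung height and a spurious vertical edge is placed
  25 mm outside it — an overlapping soft-tissue/torso edge kills the local
  lung-edge contrast while casting its own line. Injection without
  masking has no effect here: with the true outline intact, the
  nearest-edge minimum always prefers it. Capture of the fit by the
  spurious edge is an outlier mode, so the ensemble mean (not the median)
  is the statistic that grows.

What passing these studies shows: the full loop — edge detection,
silhouette correspondence, loss assembly, bounded gradient-free search,
pose/shape disentangling, volume readout — recovers known ground truth
through the actual radiograph pipeline, and degrades in the way the
method is known to degrade on poor-contrast images. What it does not
show: performance on real radiographs with ribs, mediastinal clutter,
exposure variation and landmarking error, none of which the phantom
contains; absolute error levels here are accordingly much lower than on
clinical data.

## Known limitations

* Real-data landmarking (adaptive meshing of lobes, airway
  skeletonisation) is upstream and out of scope; landmark files carry
  correspondence purely by row order.
* The 2-projection configuration performs equivalently to 1 projection on
  these phantoms (the single view already saturates); the comparison test
  asserts "no worse" rather than a strict ordering.
* The 0D solver assumes a common junction pressure (no 3D pressure field)
  and first-order volume integration.
* Airway growth can place branches outside the lung mask; diameters are a
  one-parameter geometric rule, not an anatomical regression.
* DEF patches overlap; the uniform-deposit face-mean is ≈1, not exactly 1.
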