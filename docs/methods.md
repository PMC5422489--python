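# Methods

## Problem and pipeline

DXA scanners produce a single coronal areal-BMD image (g/cm²), while
mechanistic femoral strength estimation needs a 3D finite-element model with
a 3D density distribution. `ssamfe` implements the bridge: a statistical
shape-and-appearance model (SSAM) of the proximal femur is registered to the
2D image, the reconstructed 3D shape and density are turned into an FE
model, and principal strains and femoral strength are predicted and scored
against reference data.

The stages, in pipeline order:

1. **SSAM** (`ssam`). Corresponded tetrahedral meshes with per-element
   density are stacked columnwise as `[x₁ y₁ z₁ … ; ρ₁ …]` and decomposed by
   SVD of the centered data matrix. An instance is
   `x = μ + U diag(s/√(n−1)) b` with mode weights `b` in standard scores
   (unit sample variance per mode), so GA bounds of ±3 are meaningful
   population statements. Coordinates (mm) and densities (g/cm³) carry
   different units; each block is scaled to unit total training variance
   before stacking and unscaled on instantiation. Retaining all `n−1` modes
   reproduces any training member exactly; for registration we default to
   retaining the family's effective dimensionality (the synthetic family has
   7 latent parameters, and ≥95 % of variance falls in the first 7 modes).
   Note one convention consequence: with the sample-variance (`n−1`)
   scaling, the two members of a 2-sample model sit at weights ±1/√2, not
   ±1.
2. **DRR** (`drr`). An instance is projected along the mesh y-axis
   (antero-posterior) onto the reference image grid. The default rasterizer
   distributes each element's mass over `nsub³ = 27` deterministic interior
   sample points (a volume-preserving cube→simplex lattice, de-tied and
   recentred so linear fields integrate exactly) and splats each sample
   bilinearly into its 4 nearest pixels. Bilinear splatting keeps the image
   — and hence the registration cost — smooth in the shape parameters while
   conserving mass exactly; nearest binning (`splat="nearest"`) converges to
   the exact pixel average and an analytic per-pixel ray integral
   (`method="ray"`) is available as a cross-check. Conversion uses
   1 g/cm³·mm = 0.1 g/cm².
3. **Registration** (`reconstruct`). A generational GA (tournament size 3,
   SBX crossover η=10, per-gene Gaussian mutation with geometric annealing
   of its scale from 0.15 to 0.01 of the gene range, elitism 1; population
   60, 100 generations at desk scale) minimizes the sum of three terms, each
   normalized by its value at the mean-shape/identity-pose initialization
   and weighted (1, 0.1, 0.1): the sum of absolute areal-BMD differences,
   a mesh-quality penalty (mean of 1 − mean-ratio quality, plus a large
   finite penalty per inverted element so degenerate instances are ranked,
   not rejected), and an anatomical-positioning penalty (squared in-image
   shaft tilt from vertical plus squared in-plane mass-centroid offset from
   the reference image's mass centroid). The population is seeded with the
   mean shape and ±1 standard-score single-mode candidates. Identical seed
   and configuration give bitwise-identical results.
4. **Density → modulus** (`material`). Calibration chain
   ρ_ash = 0.877·ρ_QCT + 0.079, ρ_app = ρ_ash/0.6, and the power law
   E = 6850·ρ_app^1.49 MPa (all constants config-exposed); ν = 0.3 uniform.
   Inter-mesh density transfer treats the source density as a 3D step
   function and estimates the volume-of-intersection-weighted average per
   target element by deterministic stratified sampling (64 interior points
   by default); it is exact for constant fields and for target elements
   contained in one source element. The two-step surface compensation then
   (1) raises each surface element's modulus to the maximum of its mapped
   value and its face-adjacent non-surface neighbours, and (2) caps every
   modulus at 22 GPa and floors surface moduli at 5 GPa (thin-cortex
   assumption). The compensation is idempotent.
5. **FE** (`fe`). Constant-strain tetrahedra, sparse direct solves. The
   stance case applies 4·BW·g downward, split equally over the 10 most
   superior surface nodes, with the distal cut plane fully fixed (the
   experimental potting rig is replaced by this direct fixation). The
   strength simulation is displacement-controlled in 0.05 mm increments at
   15 mm/s (Δt = 1/300 s per increment), in an incremental-tangent
   formulation: each increment assembles the stiffness from the current
   moduli, accumulates strains and reaction forces, updates each element's
   strain rate as |Δ(largest-magnitude principal strain)|/Δt, sets
   E(ε̇) = E_ref·(ε̇/ε̇_ref)^k with ε̇_ref = 5000 µε/s and k = 0.06 by
   default, and softens yielded elements to 0.55·E(ε̇) permanently. Yield
   and failure use separate tension/compression strain thresholds
   (defaults 0.73 %/1.04 % yield, 1.55 %/2.5 % failure, all config-exposed
   surrogates for values defined in cited prior work). The run stops when
   the first *surface* element fails (config switch `failure_scope="any"`
   covers the alternative reading) and the accumulated reaction on the
   driven set is the predicted strength.
6. **Validation** (`validate`). ICP registration (point-to-point, principal-
   axes pre-alignment with the incoming pose as a candidate, optional
   trimming for outliers) pairs a DIC strain cloud with FE surface elements
   through each element's smallest circumscribing sphere (closed-ball
   inclusion; empty spheres excluded). Accuracy is scored by robust
   regression — IRLS with the Tukey bisquare weight (c = 4.685, MAD scale;
   statsmodels RLM) — reporting slope, intercept, R² on the final weighted
   fit, NRMSE (RMS residual over the range of the experimental values) and
   the maximum relative prediction error over points above 10 % of the
   largest magnitude. Strength accuracy uses relative errors and
   SEE = √(mean squared residual); this root-mean-square definition
   reproduces the bundled example table's printed SEE values from its own
   entries. Shape error is unsigned point-to-surface distance; the neck
   volume difference uses exact tet/half-space clipping between two
   parallel planes perpendicular to the configured neck axis (the anatomy
   never defines the neck's limits, so the planes are configuration).

## Synthetic family

Real training data (CT-derived femur meshes) cannot ship with the package,
so `synthfem` generates a corresponded femur-like family: a generalized
cylinder swept along a centerline that runs up the shaft and bends over a
24 mm blend zone into the neck direction, with a circular cross-section
profile (constant shaft radius, smoothstep taper to the neck radius
0.65·head radius, spherical head cap). The prism layers of the swept disk
triangulation are split into tetrahedra with the minimum-vertex rule, so the
mesh is conforming and the template is built once; family members re-evaluate
the same parametric map at different latent parameters, making node
correspondence exact by construction. Densities follow a cortical shell /
trabecular interior structure with a smoothstep radial blend; zero cortical
thickness degenerates to uniform trabecular density.

Seven latent parameters are drawn uniformly per member (defaults: head
radius 19–25 mm, neck length 25–35 mm, neck-shaft angle 118–132°, shaft
radius 12–16 mm, cortical thickness 2.5–5.5 mm, trabecular density
0.20–0.40 g/cm³, cortical density 1.55–1.85 g/cm³ — ranges chosen once to
bracket adult proximal-femur anatomy and apparent densities). Device
profiles emulate the two DXA pixel geometries (1.05×0.60 mm and
0.25×0.30 mm) with additive Gaussian image noise (0.015 and
0.025 g/cm² respectively — DXA image noise varies by device and is not
standardized, so these are round values near 1–2 % of peak areal BMD, the
higher-resolution device noisier per pixel).

What the family does *not* emulate: real anatomical asymmetry (greater
trochanter, anteversion, curvature of the shaft), intra-cortical porosity
gradients, scanner beam physics (scatter, dual-energy decomposition), and
soft tissue. Passing the end-to-end tests therefore demonstrates that the
pipeline's algorithms are implemented correctly and are mutually consistent
at realistic geometric and density scales — not that clinical accuracy on
real DXA images is reproduced.

## Study conditions and problem sizes

The end-to-end recovery experiment mirrors the validation study's
conditions at desk scale: 34 training anatomies plus one held-out target,
meshes of a few thousand tetrahedra (production femur models typically use
10⁵–10⁶ elements; every algorithm here is size-agnostic), a noisy low-resolution
(Prodigy-like) reference image, GA population 60. A body weight of 75 kg
drives the 4·BW stance load. The recovered model's surface principal
strains are regressed against the ground-truth member's (majors and minor
magnitudes pooled), and the robust slope is the headline recovery metric.

## Numerical choices and degenerate inputs

- Negative-volume tets are re-oriented on construction (node swap, logged);
  degenerate elements report volume 0 and quality 0.
- The minimal enclosing sphere uses Welzl's algorithm with a least-norm
  circumsphere for degenerate support sets; tests verify against support-set
  enumeration.
- Point-to-surface queries are exact: a k-nearest-centroid pass bounds the
  distance, then every triangle within that bound plus the largest
  centroid-to-vertex radius is checked with Ericson's closest-point-on-
  triangle algorithm.
- Rays in the analytic DRR are offset by ~1.2e-5 mm so pixel columns cannot
  lie exactly in shared element faces (which would double-count).
- The linear solver verifies its residual and diagnoses the null-space
  dimension of under-constrained systems via shifted eigenvalues.
- Strain rates are floored at 1e-3 µε/s before the power law; an element
  once yielded never returns to intact; a run that does not fracture within
  the increment budget returns NaN strength and an `unfractured` flag.

## Known limitations

- The anatomical-positioning cost term is a documented stand-in; the
  original definition lives in prior work that is not reproduced here.
- The GA explores a genuinely ill-posed problem (areal BMD cannot separate
  antero-posterior thickness from density along a ray); the SSAM prior and
  the informed initialization mitigate but do not remove this, and recovery
  quality at fixed budget varies across seeds.
- Density transfer and voxel integration are sampling estimators (exact
  only for constant fields and contained elements); exact polyhedral
  clipping is a possible extension.
- The FE material model is isotropic with uniform ν; post-failure behaviour
  (crack growth, contact) is out of scope.
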