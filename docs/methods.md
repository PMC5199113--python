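# Methods

`hnmargin` implements an internal-margin (CTV→ITV) generation and
evaluation toolchain for daily pose variation in head-and-neck
radiotherapy, together with a fully synthetic phantom cohort so that
every stage is testable without patient data. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Pipeline overview

1. **Landmark stage** (`hnmargin.landmarks`). Bony landmarks represent
   the pose. Fraction positions are found by normalized
   cross-correlation (NCC) template matching in 3-D; correspondences
   with a peak score below 0.7 are dropped, as are landmarks whose
   displacement relative to same-bone neighbours is implausible under a
   Mahalanobis gate (head region > 15, shoulder region > 60; thresholds
   exclusive and configurable, including the gate direction). The rigid
   component of the daily setup error — what couch correction removes in
   image-guided treatment — is simulated by a rigid Procrustes fit
   (rotation + translation, no scaling, reflections excluded by SVD sign
   correction) on the skull landmark subset and applied to all
   landmarks. What remains per landmark is the residual deformation.
2. **Biomechanical stage** (`hnmargin.fem`). A tetrahedral model of the
   body is deformed from the planning pose toward fraction landmark
   positions through spring boundary conditions `f_i = k·d_i`
   re-evaluated at the deformed attachment points, with a homogeneous
   isotropic co-rotational linear-elastic material (default
   E = 10 MPa, ν = 0.45, k = 1000 N/mm). The dense displacement field
   follows by barycentric interpolation; structures (CTV, cord) are
   propagated through it.
3. **Statistical pose model** (`hnmargin.pose`). Per patient, couch-
   corrected landmark configurations are flattened to pose vectors
   (ℝ^{3M}, M = 24) and centered at the patient mean. The pooled cohort
   is summarized by closed-form maximum-likelihood probabilistic PCA
   (five components; noise variance = mean of discarded eigenvalues).
   Per-patient mean poses are denoised by a second five-component PPCA
   across patients (orthogonal-projection reconstruction). Pose
   scenarios are sampled with independent zero-mean Gaussian
   coefficients at the model's component variances; no isotropic noise
   is added by default (a config flag can include it).
4. **Margin engines** (`hnmargin.margins`), all on a 1 mm³ grid:
   *constant* — morphological dilation by a discretized 3 mm ball;
   *distance-weighted variable* — per-landmark, per-axis margins
   (95 % CI form `1.96 σ` or the systematic/random recipe
   `2.5 Σ + 0.7 σ`) interpolated over the CTV surface with normalized
   inverse-distance weights (exponent 3 by default) and applied as a
   spatially varying ellipsoidal dilation; *biomechanical* — each
   sampled pose scenario is solved with the FE model, the CTV is
   propagated through every scenario field, and voxels hit in strictly
   more than 5 % of scenarios form the ITV.
5. **Evaluation** (`hnmargin.evaluate`). Four metrics: planning margin
   volume V_ITV\CTV; per-fraction healthy-tissue hit V_ITV\fCTV;
   per-fraction missed CTV V_fCTV\ITV; slice-wise 3-D distance d_SC(z)
   from the ITV to the propagated spinal cord. The cohort comparison is
   leave-one-out: per-landmark statistics (approach 2) and the pose
   model (approach 3) for a patient are always fitted on the other
   patients' fractions only. Fraction ground truth (propagated CTV and
   cord) comes from the generator's analytic deformation, never from
   the fitted model, so model error is measured rather than hidden.

## The co-rotational solver

Each linear tetrahedron measures strain after removing its rotation
`R` (polar decomposition of the deformation gradient, computed by
Higham's Newton iteration with an SVD fallback for degenerate
elements), giving elastic energy `½ dᵀK_e d` with `d = Rᵀx − x₀`; rigid
motions therefore carry exactly zero energy, unlike the small-strain
linear model, which accumulates spurious strain under rotation (the
test suite quantifies this against a single-shot linear solve as
oracle).

Equilibria are computed by minimizing the total energy (elastic plus
spring). The classical warped force `R K (Rᵀx − x₀)` omits the
sensitivity of `R` to the nodal positions; with stiff springs that term
is of leading order and plain force-balance iteration stalls. The
solver therefore uses the **exact** energy gradient — the rotation
sensitivity reduces to a per-element 3×3 solve
`(tr S·I − S) w = 2 axial(skew(Rᵀ dF))`, verified against numerical
differentiation — inside an inexact Newton–Krylov loop:
finite-difference Hessian-vector products, CG preconditioned by the
spring-augmented warped stiffness, Armijo backtracking on the energy,
a rigid Procrustes warm start (the rigid-dominated part of most poses
costs zero iterations), and load stepping for pulls beyond 25 mm.
Convergence is declared when the largest nodal out-of-balance force
drops below the tolerance (default 1e-3 N; the scenario loop of the
biomechanical margin uses 0.5 N — a 0.5 N imbalance displaces a
landmark by less than 1e-3 mm at k = 1000 N/mm).

Degenerate inputs: a mesh with non-positive element volumes is
rejected; element inversion during a solve is logged, not raised; a
spring set with fewer than three non-collinear attachments skips the
rigid warm start and relies on the energy descent (a springless system
is rejected as singular).

**Known limitation.** Landmark springs are point loads lumped
barycentrically onto the containing tetrahedron. The local compliance
at a point load grows as the mesh is refined, so landmark-point
residuals keep decreasing slowly with resolution instead of
stabilizing; at the phantom's coarse resolutions, halving the cell size
moves the mean landmark residual by 10–20 %. The margin-relevant
quantity — the displacement field inside the CTV — converges
monotonically under refinement, and that is what the mesh-stability
test asserts. The E–k degeneracy (doubling both leaves the field
unchanged) holds to solver tolerance.

## Mask warping

Propagating a binary mask through a displacement field uses per-voxel
inversion of the forward field: for every voxel center `y` in a padded
band around the mask, `x ← y − u(x)` is iterated three times (the pose
fields are smooth with sub-unit gradients) and the output takes the
source voxel at `x`. This is exact for rigid motions and integer
translations and volume-faithful under smooth warps (a 10 % uniform
expansion reproduces the 1.1³ Jacobian volume ratio to 0.1 %), unlike
forward center-splatting, which loses about half a voxel of rim. The
DVF is sampled once per scenario on the cached band and interpolated
trilinearly; voxels farther from the mask than the field's maximum
displacement are skipped via a precomputed distance transform.

Voxel convention throughout: `origin` is the grid corner, centers sit
at `origin + (index + ½)·spacing`, distances are center-to-center (at
1 mm this shifts surface-gap readings by about half a voxel per
surface, which the distance tests account for).

## Margin engine details

- Constant dilation uses the lattice ball `{o : ‖o‖ ≤ r}`. The discrete
  Minkowski sum is unbiased on the total volume (the 20 mm-sphere
  oracle matches the analytic 23 mm ball within 2 %) but carries an
  ≈0.1 voxel rim deficit that is first-order on the thin shell alone.
- The variable dilation stamps each CTV surface voxel with an
  ellipsoidal element `{o : Σ (o_a/r_a)² ≤ 1}`; elements are cached
  with radii quantized to 1/8 voxel. With a constant field the result
  equals the constant dilation voxel-for-voxel (the nearest foreground
  voxel to any background voxel is always a surface voxel, so dilating
  the surface suffices).
- The scenario accumulation uses strict inequality (`count > 0.05 N`),
  so a zero threshold yields the union of all propagated CTVs.

## Synthetic phantom cohort

Geometry at desk scale: a head sphere on a neck cylinder over a
shoulder slab; a CTV horseshoe wrapped around a posterior spinal-cord
cylinder (the CTV radius is solved by bisection to hit the requested
volume, default 800 ml at full scale, 30 ml in the tiny preset); 24
landmarks (6 skull, 12 paravertebral, 6 shoulder); a structured
Kuhn-subdivision tetrahedral mesh of the body (six positively oriented
tets per cubic cell whose center lies inside; largest connected
component kept). The tiny preset uses 15 mm cells (≈1.2 k tets) — the
resolution used for the cohort runs reported by the acceptance script.

Fraction poses combine:

- a **rigid setup error** — per-axis translations with SDs
  (0.73, 1.08, 1.76) mm and rotations (1.06, 0.70, 0.92)°, the
  magnitudes reported for real IGRT cohorts; it is removed again by the
  simulated couch correction, so its parametrization does not propagate
  downstream;
- a **residual deformation** built from three fixed smooth modes
  (dominantly cranio-caudal shoulder elevation, dorsal-ventral neck
  flexion, lateral shift) scaled by a spatial weight
  `s(p) = ramp_z(z)^γ · (b + (1−b)·lat(|x|))`: zero above the skull
  base, ramping caudally with exponent γ = 1.75, and concentrated
  laterally at the shoulder girdle — the mask-stabilized spinal column
  retains only b = 0.3 of the shoulder motion. Mode amplitudes have a
  per-patient systematic component (0.4 of the random SD) plus
  per-fraction noise; the overall scale is calibrated (deterministic
  internal Monte-Carlo) so the mean shoulder-landmark motion is 9.2 mm.
  With γ = 1.75 the mean motion inside the CTV is then ≈ 1.9 mm — both
  anchors reflect the motion statistics published for real cohorts, and
  both were fixed before any margin comparison was run;
- **observation corruption** on the reported landmark sets only:
  isotropic tracking noise (SD 0.5 mm, consistent with sub-millimetre
  skull-fit errors) and 15 % missingness (the rejection rate reported
  for automatic tracking), with at least four valid skull landmarks
  kept per fraction so the couch correction stays defined. Ground
  truth — amplitudes, rigid transforms, analytic deformation functions,
  and exactly-rasterized fraction CTV/cord masks — is retained
  separately.

The generator deliberately builds its deformations from analytic
fields, not from the FE solver, so solver tests never compare the
solver against itself.

**Truth-based evaluation and the biomechanical margin.** Fraction
ground truth comes from the generator's analytic field, so the FE
model's interpolation error at tissue no landmark observes (about
1.2 mm RMS inside the CTV, mostly the anterior neck — bony landmarks
sit posteriorly and laterally, here as in real cohorts) is charged to
the biomechanical margin alone. Its missed-CTV volume therefore sits
within ~0.03 ml/fraction of the constant margin's and the comparison
can go either way between cohort draws, even though its total margin
volume is consistently far smaller. A study that propagates its
evaluation contours with the same biomechanical model would cancel
this error and flatter the biomechanical margin; measuring it was the
deliberate choice here.

**What passing tests do not show.** The phantom has no weight loss, no
swallowing or breathing motion, no CT appearance realism, identical
anatomy across patients (only posture statistics differ), and exactly
low-rank deformation modes — the PPCA model is well-specified by
construction. Cohort-level numbers from the synthetic runs are
directional analogues of a real cohort's, not predictions.

## Design choices where the design was open

- Inverse-distance weight exponent for the distance-weighted margin
  defaults to 3: Shepard weighting localizes only when the exponent is
  at least the space dimension (the number of landmarks at distance r
  grows like r^2 in 3-D, so smaller exponents let remote high-variance
  landmarks dominate the whole surface). The exponent is exposed in the
  config.
- The shoulder Mahalanobis gate defaults to removing distances
  *greater* than 60 (the plausible reading); the opposite direction is
  available via `shoulder_direction="lower"`.
- Per-landmark Mahalanobis distances aggregate over incident same-bone
  edges by the minimum, so one corrupted neighbour cannot invalidate a
  correctly tracked landmark.
- Scenario sampling anchors at the patient's denoised mean pose; the
  denoising model is fitted on the other patients (leave-one-out) and
  merely applied to the held-out patient's raw mean.
- Missing coordinates are mean-imputed within patient before the PPCA
  fit (imputation is flagged); expectation-maximization over missing
  data was judged out of proportion for ≤15 % missingness.
- The anisotropic per-axis margins are kept per-axis throughout; where
  a scalar is needed the maximum axis is used.

## Problem sizes

Unit and property tests run on the tiny phantom (15 mm cells, 30 ml
CTV). The cohort comparison used by the acceptance script and the
directional test runs 6 patients × 10 fractions with 100 sampled
scenarios per patient at scenario tolerance 0.5 N — sizes chosen so a
full run completes on a single CPU in minutes while keeping every
pipeline stage in play. All randomness flows from the single seed
passed on the command line.
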