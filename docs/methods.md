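# Methods

## Model

`longiseg` segments co-registered longitudinal multi-contrast brain MRI with
a generative model and reports longitudinal volumetry statistics.

**Segmentation prior.** Anatomy is encoded by a deformable probabilistic
atlas: a simplex mesh (triangles in 2D, tetrahedra in 3D) whose nodes carry
label probabilities. For node positions `x`, the prior over deformations is

    p(x) ∝ exp( −K Σ_m U_m(x, x_ref) ),

where `K > 0` is the mesh stiffness and `U_m` a topology-preserving cost per
simplex. The per-voxel label prior `p(l_i = k | x)` is the barycentric
interpolation of the node label probabilities inside the simplex containing
the voxel center; voxels outside the mesh support are excluded from the
analysis.

**Penalty form.** The cost per simplex is

    U_m = V_m [ (det J − 1)² + (1/det J − 1)² + ‖J − I‖²_F + ‖Δc‖² ],

with `J` the Jacobian of the affine map taking the reference simplex to the
deformed one, `V_m` the reference volume and `Δc` the centroid displacement
(voxel units). The first three terms penalize volume change and shear and
diverge as `det J → 0` (topology preservation); the centroid term removes
the translation null-space, so `U = 0` exactly and only at the identity.
During optimization a folded trial configuration (`det J ≤ 0` in either
argument) is treated as infeasible and rejected by the line search rather
than evaluated as literal infinity.

**Likelihood.** Voxel `i`'s log-transformed multi-contrast intensity vector
`d_i` given label `k` is Gaussian with a smooth additive bias field:

    p(d_i | l_i = k) = N(d_i | μ_k + C φ_i, Σ_k),

where `φ_i` stacks `P` separable cosine (DCT-II-like) basis functions and
row `n` of `C` holds contrast `n`'s bias coefficients. The first basis
function is constant, so global intensity-scaling differences between scans
are absorbed by the bias model. A consequence worth knowing when validating
recovery: the class means and the bias constant are only *jointly*
identifiable — comparisons against ground truth must align the constant
(e.g. compare `μ_k + mean(bias)`).

**Cross-sectional fitting.** The log-posterior

    F(x, θ) = Σ_i log Σ_k N(d_i | μ_k + Cφ_i, Σ_k) p(l_i = k | x)
              − K Σ_m U_m(x, x_anchor)

is maximized by coordinate ascent: a few EM steps for θ (responsibilities →
Gaussian parameters → exact weighted-least-squares bias update, which solves
the coupled multi-contrast normal equations) alternate with a quasi-Newton
ascent over mesh positions. Every block update increases `F`, so the
recorded objective trace is monotone — an invariant the test suite asserts
on every fit. Labels are the per-voxel argmax of the class posteriors, ties
toward the lowest class index.

**Longitudinal coupling.** A subject's `T` time points share two latent
variables: latent mesh positions `x0` (the average subject anatomy), with

    p(x_t | x0) ∝ exp(−K Σ_m U_m(x_t, x0)),
    p(x0) ∝ exp(−K0 Σ_m U_m(x0, x_ref)),

and latent Gaussian prototypes `θ0 = {μ0_k, Σ0_k}` under a
normal-inverse-Wishart coupling of each time point's Gaussian parameters:

    p(θ_t | θ0) ∝ Π_k N(μ_{t,k} | μ0_k, P0_k⁻¹ Σ_{t,k})
                      IW(Σ_{t,k} | P0_k Σ0_k, P0_k − N − 2),

with flat priors on θ0 and the bias parameters (bias varies between
sessions and is never coupled). The degrees-of-freedom convention makes the
per-time-point MAP update collapse to the ML update as `P0_k → 0`; with
`P0 = 0` and very large `K0` the model reduces exactly to independent
cross-sectional fits, which the acceptance suite verifies at the label
level. For `P0_k ≤ 2N + 1` the IW factor is improper; the posterior-mode
update remains well-defined and is used as-is (a warning is raised), while
density evaluations clamp the degrees of freedom just above the properness
bound.

**Joint fitting.** An unbiased within-subject template (voxelwise median
across time points — inputs are assumed co-registered, so no registration is
performed) is fitted cross-sectionally; its estimates initialize every
`x_t, θ_t` and the latents `x0, θ0`. Five global coordinate-ascent
iterations follow (the default, exposed in configuration): for each time
point, two EM steps with the NIW pull plus one mesh ascent anchored at
`x0`; then the closed-form prototype updates

    μ0_k ← (Σ_t Σ_{t,k}⁻¹)⁻¹ Σ_t Σ_{t,k}⁻¹ μ_{t,k},
    Σ0_k⁻¹ ← (1/T) Σ_t Σ_{t,k}⁻¹ · P0_k / (P0_k − N − 2),

which are the exact maximizers of the summed coupling density (verified in
the tests against a numeric optimizer on a Cholesky parameterization), and
an L-BFGS update of `x0` minimizing
`K0 Σ U(x0, x_ref) + K Σ_t Σ U(x_t, x0)`. The joint objective is
non-decreasing across global iterations. Prototypes of classes with
`P0_k = 0` are unused and left untouched.

**Hyperparameters.** `K0 = 20 K` and `P0_k = 0.5 N_k`, with `N_k` the voxel
count of class k in the template segmentation. These are the model's
defaults; both are overridable. Classes with empty template counts get
`P0_k = 0`.

**Lesions.** White-matter lesions are one extra Gaussian class whose
spatial prior is the white-matter prior scaled by a mixing weight (default
0.05) and whose parameters are *never* coupled over time (`P0 = 0` at every
time point) — lesion load changes too abruptly for prototype shrinkage.
Three constraints stand in for the full lesion-shape model that the
production method obtains from a learned shape prior:

1. hyperintensity projection — after every update the lesion mean in the
   designated contrast is clipped to at least the white-matter mean;
2. a covariance floor in the Loewner order (lesion covariance ⪰ white-matter
   covariance): lesion tissue is at least as heterogeneous as
   normal-appearing white matter, which stops the lesion Gaussian from
   collapsing onto the bright tail of the white-matter distribution when no
   lesions exist;
3. a minimum lesion-component size (default 5 voxels) applied to the
   binarized mask (posterior responsibility > 0.5): isolated supra-threshold
   voxels are noise, not lesions. Without it, the posterior decision
   boundary sits near 2.75 white-matter SDs and ~0.3% of white-matter voxels
   cross it by chance alone.

The symmetry between the white-matter and lesion Gaussians at
initialization is broken by offsetting the lesion mean by 3 SD in the
lesion-visible contrast; classes whose responsibility mass is too small to
estimate keep their previous parameters instead of erroring.

## Synthetic phantoms

The generator samples data exactly the way the model assumes they arise —
which is the point: it provides ground truth for every latent quantity, so
parameter recovery, segmentation accuracy, volumetric tracking, test–retest
reliability and group-difference detection can all be measured exactly.

* **Anatomy**: a concentric toy atlas (background / gray matter / white
  matter / ventricle by default; 2–5 classes) with logistic boundary
  profiles (scale 1 voxel) truncated below 5e-3 so each structure's prior
  support is compact. Mesh node spacing defaults to 6 voxels.
* **Subject deformation**: a smooth random node displacement (Gaussian
  field over the node lattice, RMS 1 voxel by default), tapered to zero at
  the mesh boundary, re-scaled until unfolded.
* **Atrophy**: per-structure volume-change rates in %/yr on a *linear*
  trajectory `v(t) = v(0)(1 + r t/100)`, so the annualized-percent-change
  statistic of an exactly recovered phantom equals the prescribed rate. The
  radial warp that realizes a rate is a pure (affine) scaling throughout a
  band covering the structure's entire prior support plus one simplex layer;
  because affine maps are represented exactly by the mesh, the deformed
  label region's volume changes by exactly the prescribed factor. The
  expected (partial-volume) volumes under the deformed prior track the
  prescription to ~0.1%; hard-label *counts* additionally carry
  lattice-discretization jitter of up to ~1.5% at these structure sizes
  (the same jitter arises when counting lattice points in perfect disks),
  which is why self-checks of the prescription use the expected volumes.
* **Intensities**: per-class correlated Gaussian draws (default SD 0.1 in
  log units, inter-contrast correlation 0.3; class separations 4–6 SD —
  "high SNR"), plus a random smooth bias field drawn from the same cosine
  family the model fits (order 2 per axis, coefficient SD = half the
  amplitude parameter, default amplitude 0.1).
* **Lesions**: circular blobs (default 2 of radius 3) placed inside white
  matter, intensities drawn from the white-matter Gaussian shifted +4 SD in
  the designated contrast.

What the generator does **not** emulate: scanner point-spread, motion,
Rician noise, partial-volume mixing at acquisition, misregistration between
time points or contrasts, and any real anatomical variability beyond smooth
mesh deformations. Passing phantoms therefore demonstrates correctness of
the estimation machinery under the model's own assumptions — not robustness
to model mismatch on clinical data.

## Experiment conditions used by the test suite

* Special-case reduction: 48³ voxels, K=4, T=3, −4%/yr ventricular change;
  the uncoupled longitudinal fit must agree with matched independent
  cross-sectional fits on ≥ 99.9% of voxels.
* Parameter recovery: 48³ high-SNR phantom at the generator defaults; class
  means (constant-aligned) within 2%, bias-field correlation r > 0.99,
  per-class Dice ≥ 0.9.
* Test–retest: 20 subjects × 2 identical-anatomy scans with independent
  noise and bias at noise SD 0.25 (at the default SD 0.1 both methods
  reproduce volumes exactly and the comparison degenerates to a 0–0 tie);
  median structure-wise ASPC longitudinal ≤ cross-sectional.
* Atrophy sensitivity: n=10 per group, T=3 (years 0,1,2), ventricular rates
  −3%/yr vs 0%/yr with 1%/yr between-subject SD, 64² grids; estimated-APC
  Cohen's d > 1 and mean APC bias < 1.5%/yr.
* Lesion extension: 96², two contrasts, 2 blobs of radius 3 (+4 SD, ~3% of
  white matter): Dice ≥ 0.7; lesion-free phantom: false positives ≤ 0.1% of
  white matter.
* `scripts/acceptance.py` recomputes the same quantities with the
  model-reduction, recovery and lesion experiments run in 2D (where the
  estimation machinery is identical and the statistics are the same), and
  the test–retest and cohort experiments at their full sizes; each JSON
  entry records the size used.

## Numerical choices

* **Optimizer**: a compact two-loop L-BFGS ascent with Armijo backtracking
  (memory 8, unit-scaled first step). Trial points with folded simplices
  evaluate as infeasible and shrink the step — this is why scipy's bounded
  optimizers are not used here. Every accepted step strictly improves the
  objective, which is what makes the coordinate-ascent traces monotone.
* **Point location**: rasterization assigns each voxel center to the
  lowest-index containing simplex (deterministic tie-break, boundary
  tolerance 1e-9). Inside mesh optimization a warm-started cache verifies
  the previous assignment, repairs failures via node-sharing neighbor
  simplices, and falls back to a full search — interpolated fields are
  identical because barycentric interpolation is continuous across faces.
* **Covariance hygiene**: eigenvalue flooring at 1e-8 of the mean
  eigenvalue keeps covariances SPD under near-degenerate responsibilities;
  a class whose total responsibility falls below 10 voxels with no prior to
  regularize it raises a degenerate-class error (fitting loops may instead
  freeze such a class, used by the lesion path).
* **Log-domain throughout**: responsibilities and the evidence use
  log-sum-exp; zero priors contribute −∞ cleanly; a voxel with no
  admissible class raises an error naming the voxel row.
* **Schedules** (all exposed in `FitOptions`): cross-sectional — 3 EM steps
  and 1 mesh ascent (≤ 20 L-BFGS iterations) per outer iteration, at most
  30 outer iterations, relative-change tolerance 1e-5; longitudinal — 5
  global iterations with 2 EM steps + 1 mesh ascent per time point.
  Initialization: prior-weighted moments under the undeformed atlas
  (classes without prior mass fall back to global moments), zero bias.
* **Degenerate inputs**: meshes folded in either argument, mismatched
  grids/contrasts/masks across time points, all-zero images, rates that
  collapse a structure, and prescribed structures too close together for an
  exact warp all raise informative errors rather than proceeding.

## Limitations

* Registration and resampling are preconditions, not features: the tool
  refuses mismatched grids. The production pipeline's inverse-consistent
  template registration is out of scope.
* One Gaussian per class; no Gaussian sharing or mixtures per structure, no
  Rician noise model, no spatially varying covariance.
* The lesion extension replaces the learned lesion-shape prior with the
  three constraints above; lesion subtyping and new/enlarging-lesion
  detection are out of scope.
* The toy atlases are concentric idealizations; nothing here validates
  anatomical plausibility on real brains.
* Volumes from hard label counts inherit lattice-discretization jitter
  (sub-voxel surface placement is not estimated); on small structures this
  bounds how precisely a prescribed trajectory can be read back from
  counts.
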