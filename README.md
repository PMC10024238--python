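# longiseg

Longitudinal whole-brain and white-matter-lesion segmentation of
multi-contrast MRI with a generative model, plus the volumetry statistics
used to study disease progression (atrophy rates, test–retest reliability,
group effect sizes, lesion change rates).

## Who this is for

Neuroimaging researchers who follow the same subject across multiple MRI
sessions and need *temporally consistent* segmentations: independent
per-scan segmentation injects session-to-session noise into volume
trajectories, inflating test–retest variability and diluting group
differences in atrophy rates. `longiseg` couples a subject's time points
through subject-specific latent variables so that measurement noise shrinks
while real anatomical change remains free to express itself — no particular
temporal trajectory (e.g. monotone decline) is imposed.

## The model

Per scan, a cross-sectional generative model:

* a **deformable probabilistic atlas** — a simplex mesh with label
  probabilities at its nodes; deformation away from the reference positions
  `x_ref` is penalized by a topology-preserving cost
  `p(x) ∝ exp(−K Σ_m U_m(x, x_ref))`, and the voxelwise label prior
  `p(l_i = k | x)` is barycentric interpolation;
* a **Gaussian likelihood with bias field** on log-intensities,
  `p(d_i | l_i = k) = N(d_i | μ_k + C φ_i, Σ_k)`, with `φ_i` smooth cosine
  basis functions, so scanner bias and global scaling are estimated jointly
  with the segmentation.

Longitudinally, a subject's `T` scans share latent average anatomy `x0`
(each `x_t` is anchored to it with stiffness `K`, and `x0` to the atlas with
stiffness `K0`) and latent intensity prototypes `{μ0_k, Σ0_k}` that couple
each scan's Gaussians through a normal-inverse-Wishart prior of per-class
strength `P0_k`:

    p(θ_t | θ0) ∝ Π_k N(μ_{t,k} | μ0_k, P0_k⁻¹ Σ_{t,k})
                      IW(Σ_{t,k} | P0_k Σ0_k, P0_k − N − 2).

Defaults `K0 = 20 K` and `P0_k = 0.5 N_k` (template voxel counts). Setting
`P0 = 0` and `K0 → ∞` recovers independent cross-sectional segmentation
exactly. Fitting is coordinate ascent (EM for intensities, quasi-Newton for
meshes, closed-form prototype updates); segmentation is the per-voxel MAP
label. An optional lesion class — an extra Gaussian restricted to plausible
white-matter locations and constrained to be hyperintense in a designated
contrast — is deliberately *not* coupled over time.

Included metrics: ASPC / SPC (symmetrized percent change between two
scans), APC (annualized percent change from an OLS line, slope over
baseline intercept), Cohen's d and a power-based sample-size estimate
between patient groups, lesion increase/decrease rates (LES_I / LES_D),
and Dice overlap. A synthetic-phantom generator samples complete
longitudinal subjects (and cohorts) from the model itself, with ground-truth
labels, deformations, bias fields, volumes and lesions.

## Worked example

Simulate a 2-year, 2-scan subject whose ventricle-like structure shrinks by
5 %/yr, fit the longitudinal model, and read off the atrophy rate:

```bash
longiseg simulate --out demo --grid 64x64 --timepoints 0,1 \
    --rate ventricle=-5 --seed 3
longiseg fit-long --manifest demo/manifest.yaml --atlas demo/atlas.npz \
    --out demo/fit
longiseg metrics apc --volumes demo/fit/volumes.csv \
    --structure ventricle --times 0,1
longiseg metrics dice --mask-x demo/fit/labels_tp0.nii.gz \
    --mask-y demo/truth_labels_tp0.nii.gz --label 3
```

Output of the last two commands:

```
-4.838710
1.000000
```

i.e. the fitted ventricle volumes (`demo/fit/volumes.csv`: 0.248 ml →
0.236 ml) give an annualized change of −4.84 %/yr against the prescribed
−5 %/yr — the residual is the voxel-counting granularity of a structure
this small, not segmentation error, as the perfect Dice of 1.0 against the
ground-truth label map shows. `demo/fit/report.json` records the
(monotone) joint-objective trace and the hyperparameters used.

The same pipeline is available as a library:

```python
from longiseg import PhantomSpec, simulate_subject, fit_longitudinal

images, truth = simulate_subject(PhantomSpec(
    grid_shape=(96, 96), times=(0.0, 1.0, 2.0),
    rates={"ventricle": -5.0}, seed=11))
result = fit_longitudinal(images, truth.atlas)
print(result.volumes.loc["ventricle"])   # t0 0.623, t1 0.591, t2 0.552 ml
```

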