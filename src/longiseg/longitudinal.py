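"""Longitudinal model: subject-specific latent variables couple time points.

Each subject contributes T co-registered scans.  Two latent variables tie
the per-time-point models together:

* ``x0`` — latent atlas node positions encoding the average subject anatomy.
  Each time point's mesh ``x_t`` is penalized for deforming away from ``x0``
  (stiffness K), and ``x0`` itself is penalized for deforming away from the
  atlas reference (stiffness ``K0``).
* ``theta0 = {mu0_k, Sigma0_k}`` — prototype Gaussian intensity parameters.
  Each time point's class Gaussians carry a normal-inverse-Wishart prior
  centered on the prototypes with per-class strength ``P0_k``.

Fitting maximizes the joint posterior over all latents and per-time-point
parameters by coordinate ascent: per-time-point sweeps (EM for theta_t, mesh
ascent for x_t) alternate with closed-form prototype updates and a
quasi-Newton update of x0.  With ``P0 = 0`` and very large ``K0`` every
coupling disappears and the method reduces to independent cross-sectional
fits — a special case kept exact here and exercised in the tests.

Hyperparameter defaults follow the ``K0 = 20 K`` and ``P0_k = 0.5 N_k``
rule, with ``N_k`` the voxel count of class k in the segmentation of the
within-subject template.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import intensity as inten
from . import mesh as meshmod
from .cross_sectional import (FitOptions, FitResult, LabelMap, _em_step,
                              _aligned_prior, fit_cross_sectional,
                              optimize_mesh, segment, structure_volumes)
from .mesh import FoldedMeshError, MembershipCache, SimplexAtlas
from .optim import lbfgs_maximize

__all__ = [
    "SubjectLatents",
    "LongHyperparams",
    "LongFitResult",
    "build_template",
    "derive_hyperparameters",
    "update_theta0",
    "update_x0",
    "fit_longitudinal",
]


@dataclasses.dataclass
class SubjectLatents:
    """Latent mesh positions and intensity prototypes of one subject."""

    x0: np.ndarray
    proto_means: np.ndarray  # (K, N)
    proto_covs: np.ndarray  # (K, N, N)


@dataclasses.dataclass
class LongHyperparams:
    K0: float
    P0: np.ndarray  # (K,)

    def __post_init__(self):
        self.P0 = np.asarray(self.P0, dtype=float)
        if not self.K0 > 0:
            raise ValueError("K0 must be positive")
        if np.any(self.P0 < 0):
            raise ValueError("P0 must be nonnegative")


@dataclasses.dataclass
class LongFitResult:
    timepoint_fits: list  # per-time-point FitResult
    latents: SubjectLatents
    hyper: LongHyperparams
    objective_trace: list
    label_maps: list
    volumes: pd.DataFrame  # structures x time points, ml
    template_fit: FitResult


def build_template(images) -> inten.ImageData:
    """Voxelwise median across time points per contrast.

    A robust stand-in for the average subject anatomy; inputs must already
    be co-registered and resampled to one grid.  T = 1 returns the image
    unchanged.
    """
    if len(images) == 0:
        raise ValueError("no images")
    first = images[0]
    for im in images[1:]:
        if im.grid_shape != first.grid_shape:
            raise ValueError(
                f"grid mismatch: {im.grid_shape} vs {first.grid_shape}")
        if not np.array_equal(im.mask, first.mask):
            raise ValueError("masks differ across time points")
        if im.n_contrasts != first.n_contrasts:
            raise ValueError("contrast counts differ across time points")
    if len(images) == 1:
        return first
    stack = np.stack([im.log_intensities for im in images])
    return inten.ImageData(
        log_intensities=np.median(stack, axis=0),
        mask=first.mask, grid_shape=first.grid_shape,
        voxel_size=first.voxel_size, timepoint_time=0.0)


def derive_hyperparameters(template_labels: LabelMap,
                           atlas: SimplexAtlas) -> LongHyperparams:
    """K0 = 20 K and P0_k = 0.5 N_k from the template segmentation."""
    K = len(template_labels.class_names)
    sel = template_labels.labels[template_labels.labels >= 0]
    counts = np.bincount(sel.ravel(), minlength=K)[:K]
    return LongHyperparams(K0=20.0 * atlas.stiffness, P0=0.5 * counts)


def update_theta0(per_timepoint_params, P0):
    """Closed-form update of the intensity prototypes.

    mu0_k is the precision-weighted mean of the time-point means and

        Sigma0_k^{-1} = (1/T) sum_t Sigma_{t,k}^{-1} * P0_k / (P0_k - N - 2).

    Classes with ``P0_k = 0`` get the natural uncoupled analogues (the
    precision-weighted mean and the harmonic-mean covariance); their
    prototypes are never used by the coupled updates.
    """
    models = list(per_timepoint_params)
    if len(models) == 0:
        raise ValueError("no time points")
    K, N = models[0].means.shape
    P0 = np.broadcast_to(np.asarray(P0, dtype=float), (K,))
    proto_means = np.empty((K, N))
    proto_covs = np.empty((K, N, N))
    for k in range(K):
        if 0 < P0[k] <= N + 2:
            raise ValueError(
                f"P0 for class {k} is {P0[k]:.3g} <= N + 2 = {N + 2}: the "
                "prototype covariance update is undefined")
        precisions = [np.linalg.inv(m.covariances[k]) for m in models]
        prec_sum = np.sum(precisions, axis=0)
        proto_means[k] = np.linalg.solve(
            prec_sum, np.sum([P @ m.means[k]
                              for P, m in zip(precisions, models)], axis=0))
        factor = P0[k] / (P0[k] - N - 2) if P0[k] > 0 else 1.0
        proto_covs[k] = np.linalg.inv(prec_sum / len(models) * factor)
        proto_covs[k] = (proto_covs[k] + proto_covs[k].T) / 2.0
    return proto_means, proto_covs


def update_x0(xt_list, x0_init, atlas: SimplexAtlas, K0, max_iter=30):
    """Quasi-Newton minimization of the latent-mesh objective

        K0 sum_m U_m(x0, x_ref) + K sum_t sum_m U_m(x_t, x0).

    Returns an unfolded configuration with objective no higher than at
    ``x0_init``.
    """
    x0_init = atlas.check_positions(x0_init)
    K = atlas.stiffness
    if not np.isfinite(meshmod.simplex_penalty(x0_init, atlas.ref_positions,
                                               atlas)):
        raise FoldedMeshError("x0_init is folded")

    def fun_grad(x0):
        pen0 = meshmod.simplex_penalty(x0, atlas.ref_positions, atlas)
        if not np.isfinite(pen0):
            return -np.inf, None
        val = -K0 * pen0
        grad = -K0 * meshmod.penalty_gradient(x0, atlas.ref_positions, atlas,
                                              wrt="deformed")
        for xt in xt_list:
            pen_t = meshmod.simplex_penalty(xt, x0, atlas)
            if not np.isfinite(pen_t):
                return -np.inf, None
            val -= K * pen_t
            grad -= K * meshmod.penalty_gradient(xt, x0, atlas,
                                                 wrt="reference")
        return val, grad

    x0_opt, _, _ = lbfgs_maximize(fun_grad, x0_init, max_iter=max_iter)
    return x0_opt


def _joint_objective(images, atlas, fits_mesh, fits_model, bases, latents,
                     hyper, caches):
    val = -hyper.K0 * meshmod.simplex_penalty(latents.x0, atlas.ref_positions,
                                              atlas)
    for t, im in enumerate(images):
        prior = _aligned_prior(fits_mesh[t], atlas, caches[t], im)
        val += inten.log_evidence(im, fits_model[t], bases[t], prior)
        val -= atlas.stiffness * meshmod.simplex_penalty(
            fits_mesh[t], latents.x0, atlas)
        for k in range(fits_model[t].n_classes):
            if hyper.P0[k] > 0:
                val += inten.niw_logpdf(
                    fits_model[t].means[k], fits_model[t].covariances[k],
                    latents.proto_means[k], latents.proto_covs[k],
                    hyper.P0[k])
    return val


def fit_longitudinal(images, atlas: SimplexAtlas, hyper="auto",
                     opts: FitOptions = None, n_global=5,
                     n_em_per_sweep=2, template_fit: FitResult = None
                     ) -> LongFitResult:
    """Joint fit of all time points with subject-specific latent coupling.

    Pipeline: build the within-subject template, fit it cross-sectionally,
    use the template estimates to initialize every time point and the
    latents, then run ``n_global`` coordinate-ascent iterations alternating
    per-time-point updates (EM for the Gaussians and bias, mesh ascent
    anchored at x0) with the closed-form prototype update and the x0
    optimization.  Finally each time point is segmented with its own fitted
    parameters.
    """
    if len(images) == 0:
        raise ValueError("no images")
    opts = opts or FitOptions()
    template = build_template(images)
    if template_fit is None:
        template_fit = fit_cross_sectional(template, atlas, opts)

    if isinstance(hyper, str):
        if hyper != "auto":
            raise ValueError("hyper must be LongHyperparams or 'auto'")
        template_labels = segment(template, atlas, template_fit.mesh,
                                  template_fit.intensity, template_fit.basis)
        hyper = derive_hyperparameters(template_labels, atlas)

    T = len(images)
    meshes = [template_fit.mesh.copy() for _ in range(T)]
    models = [template_fit.intensity.copy() for _ in range(T)]
    bases = [template_fit.basis for _ in range(T)]
    latents = SubjectLatents(
        x0=template_fit.mesh.copy(),
        proto_means=template_fit.intensity.means.copy(),
        proto_covs=template_fit.intensity.covariances.copy())
    caches = [MembershipCache(atlas) for _ in range(T)]

    sweep_opts = dataclasses.replace(
        opts, prototypes=(latents.proto_means, latents.proto_covs),
        P0=hyper.P0, anchor=None)

    trace = [_joint_objective(images, atlas, meshes, models, bases, latents,
                              hyper, caches)]
    for _ in range(n_global):
        sweep_opts.prototypes = (latents.proto_means, latents.proto_covs)
        for t, im in enumerate(images):
            prior = _aligned_prior(meshes[t], atlas, caches[t], im)
            for _ in range(n_em_per_sweep):
                models[t] = _em_step(im, models[t], bases[t], prior,
                                     sweep_opts)
                if opts.constraint is not None:
                    models[t] = opts.constraint(models[t])
            meshes[t] = optimize_mesh(im, atlas, meshes[t], latents.x0,
                                      atlas.stiffness, models[t], bases[t],
                                      opts, cache=caches[t])
        proto_means, proto_covs = update_theta0(models, hyper.P0)
        coupled = hyper.P0 > 0
        latents.proto_means[coupled] = proto_means[coupled]
        latents.proto_covs[coupled] = proto_covs[coupled]
        latents.x0 = update_x0(meshes, latents.x0, atlas, hyper.K0)
        trace.append(_joint_objective(images, atlas, meshes, models, bases,
                                      latents, hyper, caches))

    label_maps = [segment(im, atlas, meshes[t], models[t], bases[t])
                  for t, im in enumerate(images)]
    vols = pd.DataFrame(
        {f"t{t}": structure_volumes(lm, images[t].voxel_size)
         for t, lm in enumerate(label_maps)})
    fits = [FitResult(mesh=meshes[t], intensity=models[t],
                      objective_trace=[], converged=True, n_iterations=0,
                      basis=bases[t]) for t in range(T)]
    return LongFitResult(timepoint_fits=fits, latents=latents, hyper=hyper,
                         objective_trace=trace, label_maps=label_maps,
                         volumes=vols, template_fit=template_fit)
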