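"""Cross-sectional model fitting and MAP segmentation.

Fitting maximizes the log-posterior

    F(x, theta) = sum_i log sum_k N(d_i | mu_k + C phi_i, Sigma_k) p(l_i=k | x)
                  - K sum_m U_m(x, x_anchor)   [+ log NIW priors if coupled]

by coordinate ascent: a few EM steps for the intensity parameters theta
(responsibilities, Gaussian parameters, bias field) alternate with a
quasi-Newton ascent over the mesh node positions x.  The anchor of the mesh
penalty is the atlas reference position in the cross-sectional case and the
subject-specific latent mesh in the longitudinal one; likewise the Gaussian
update may carry a normal-inverse-Wishart pull toward subject prototypes.
Segmentation is the per-voxel argmax of the class posteriors.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import intensity as inten
from . import mesh as meshmod
from .mesh import FoldedMeshError, MembershipCache, SimplexAtlas
from .optim import lbfgs_maximize

__all__ = [
    "FitOptions",
    "FitResult",
    "LabelMap",
    "optimize_mesh",
    "fit_cross_sectional",
    "segment",
    "structure_volumes",
]


@dataclasses.dataclass
class FitOptions:
    """Knobs of the coordinate-ascent fit.

    ``n_em`` EM steps per outer iteration, one mesh optimization per outer
    iteration, stopping when the relative objective change drops below
    ``tol`` or after ``max_outer`` iterations.
    """

    n_em: int = 3
    max_outer: int = 30
    tol: float = 1e-5
    mesh_max_iter: int = 20
    bias_order: tuple = None  # default: 2 per dimension
    init_mesh: np.ndarray = None
    init_model: "inten.IntensityModel" = None
    anchor: np.ndarray = None
    stiffness: float = None
    prototypes: tuple = None  # (proto_means, proto_covs)
    P0: np.ndarray = None
    constraint: Optional[Callable] = None  # model -> model, applied post-update
    on_degenerate: str = "error"  # or "freeze"


@dataclasses.dataclass
class FitResult:
    mesh: np.ndarray
    intensity: "inten.IntensityModel"
    objective_trace: list
    converged: bool
    n_iterations: int
    basis: "inten.BiasBasis" = None


@dataclasses.dataclass
class LabelMap:
    """Class indices on the analyzed voxels; -1 outside the mask."""

    labels: np.ndarray
    class_names: list
    mask: np.ndarray = None

    @property
    def grid_shape(self):
        return self.labels.shape


def _aligned_prior(x, atlas, cache, data):
    simp, w, vox = cache.query(x)
    nodes = atlas.simplices[simp]
    probs = np.einsum("nj,njk->nk", w, atlas.node_label_probs[nodes])
    np.clip(probs, 0.0, None, out=probs)
    probs /= probs.sum(axis=1, keepdims=True)
    field = meshmod.LabelPriorField(probs=probs, voxel_index_map=vox,
                                   grid_shape=atlas.grid_shape)
    return inten.prior_on_mask(field, data)


def _mesh_objective_parts(x, atlas, cache, data, log_lik):
    """Data term and its gradient w.r.t. node positions at fixed theta.

    Returns ``(value, grad)`` or ``(-inf, None)`` on folded/uncovering
    configurations.
    """
    try:
        simp, w, vox = cache.query(x)
    except FoldedMeshError:
        return -np.inf, None
    flat = data.flat_indices
    pos = np.searchsorted(vox, flat)
    inside = (pos < vox.size) & (vox[np.minimum(pos, vox.size - 1)] == flat)
    if not np.all(inside):
        # a masked voxel slipped outside the mesh: treat as infeasible so the
        # line search backs off rather than silently changing the data set
        return -np.inf, None
    rows = pos
    simp = simp[rows]
    w = w[rows]
    nodes = atlas.simplices[simp]  # (I, D+1)
    q = atlas.node_label_probs[nodes]  # (I, D+1, K)
    pi = np.einsum("nj,njk->nk", w, q)
    np.clip(pi, 0.0, None, out=pi)
    with np.errstate(divide="ignore"):
        log_post = log_lik + np.log(pi)
    s = logsumexp(log_post, axis=1)
    if not np.all(np.isfinite(s)):
        return -np.inf, None
    value = float(s.sum())

    Gn = np.exp(log_lik - s[:, None])  # (I, K): G_ik / s_i
    c = np.einsum("nk,njk->nj", Gn, q)  # dF/dlambda_j
    verts = x[atlas.simplices[simp]]
    D = atlas.ndim
    A = np.swapaxes(verts[:, 1:, :] - verts[:, :1, :], 1, 2)
    Ainv = np.linalg.inv(A)
    vec = c[:, 1:] - c[:, :1]  # (I, D)
    r = np.einsum("nd,ndj->nj", vec, Ainv)  # (I, D)
    contrib = -w[:, :, None] * r[:, None, :]  # (I, D+1, D)
    grad = np.zeros_like(x)
    np.add.at(grad, nodes.ravel(), contrib.reshape(-1, D))
    return value, grad


def optimize_mesh(data, atlas: SimplexAtlas, x_init, x_anchor, stiffness,
                  intensity_model, basis, opts: FitOptions = None,
                  cache: MembershipCache = None):
    """Ascend the mesh-position objective at fixed intensity parameters.

    Never returns a folded mesh and never decreases the objective relative
    to ``x_init``.
    """
    opts = opts or FitOptions()
    x_init = atlas.check_positions(x_init)
    x_anchor = atlas.check_positions(x_anchor)
    if not np.isfinite(meshmod.simplex_penalty(x_init, x_anchor, atlas)):
        raise FoldedMeshError("x_init is folded")
    cache = cache or MembershipCache(atlas)
    log_lik = inten.class_log_likelihoods(data, intensity_model, basis)

    def fun_grad(x):
        data_val, data_grad = _mesh_objective_parts(x, atlas, cache, data,
                                                    log_lik)
        if not np.isfinite(data_val):
            return -np.inf, None
        pen = meshmod.simplex_penalty(x, x_anchor, atlas)
        if not np.isfinite(pen):
            return -np.inf, None
        grad = data_grad - stiffness * meshmod.penalty_gradient(
            x, x_anchor, atlas, wrt="deformed"
        )
        return data_val - stiffness * pen, grad

    x_opt, _, _ = lbfgs_maximize(fun_grad, x_init,
                                 max_iter=opts.mesh_max_iter)
    return x_opt


def _init_model(data, atlas, cache, basis, opts):
    """Prior-weighted moments under the undeformed atlas; classes with
    (almost) no prior mass fall back to the global data moments."""
    prior = _aligned_prior(atlas.ref_positions if opts.init_mesh is None
                           else opts.init_mesh, atlas, cache, data)
    C0 = np.zeros((data.n_contrasts, basis.n_funcs))
    K = prior.shape[1]
    N = data.n_contrasts
    vals = data.log_intensities
    g_mean = vals.mean(axis=0)
    g_cov = np.cov(vals.T, ddof=0).reshape(N, N)
    means = np.tile(g_mean, (K, 1))
    covs = np.tile(_floor_spd(g_cov), (K, 1, 1))
    mass = prior.sum(axis=0)
    for k in range(K):
        if mass[k] < 10:
            continue
        mu = (prior[:, k] @ vals) / mass[k]
        diff = vals - mu
        cov = (prior[:, k, None] * diff).T @ diff / mass[k]
        means[k] = mu
        covs[k] = _floor_spd(cov)
    return inten.IntensityModel(means=means, covariances=covs, bias_coeffs=C0,
                                class_names=list(atlas.class_names))


def _floor_spd(cov):
    n = cov.shape[-1]
    w, V = np.linalg.eigh((cov + cov.T) / 2.0)
    floor = max(1e-8 * np.trace(cov) / n, 1e-12)
    return (V * np.maximum(w, floor)) @ V.T


def _objective(data, model, basis, prior, x, anchor, atlas, stiffness,
               prototypes=None, P0=None):
    val = inten.log_evidence(data, model, basis, prior)
    val -= stiffness * meshmod.simplex_penalty(x, anchor, atlas)
    if prototypes is not None and P0 is not None:
        for k in range(model.n_classes):
            if P0[k] > 0:
                val += inten.niw_logpdf(model.means[k], model.covariances[k],
                                        prototypes[0][k], prototypes[1][k],
                                        P0[k])
    return val


def _em_step(data, model, basis, prior_aligned, opts):
    resp = inten.compute_responsibilities(data, model, basis, prior_aligned)
    try:
        means, covs = inten.update_gaussians(
            data, resp, basis, model.bias_coeffs,
            prototypes=opts.prototypes, P0=opts.P0)
    except inten.DegenerateClassError:
        if opts.on_degenerate != "freeze":
            raise
        means, covs = _update_with_freeze(data, resp, basis, model, opts)
    C = inten.update_bias(data, resp, means, covs, basis)
    return inten.IntensityModel(means=means, covariances=covs, bias_coeffs=C,
                                class_names=model.class_names)


def _update_with_freeze(data, resp, basis, model, opts):
    """Per-class update that keeps a class's previous parameters when its
    responsibility mass is too small to estimate them (and no prior helps)."""
    K = model.n_classes
    means = model.means.copy()
    covs = model.covariances.copy()
    for k in range(K):
        w1 = resp.weights[:, [k]]
        sub = inten.Responsibilities(
            weights=np.concatenate([w1, 1.0 - w1], axis=1))
        protos = None
        P0k = None
        if opts.prototypes is not None and opts.P0 is not None:
            protos = (np.stack([opts.prototypes[0][k], model.means[k]]),
                      np.stack([opts.prototypes[1][k], model.covariances[k]]))
            P0k = np.array([opts.P0[k], 0.0])
        try:
            m2, c2 = inten.update_gaussians(
                data, sub, basis, model.bias_coeffs,
                prototypes=protos,
                P0=P0k if P0k is not None else np.array([0.0, 0.0]),
                min_voxels=10)
            means[k], covs[k] = m2[0], c2[0]
        except inten.DegenerateClassError:
            pass  # freeze class k
    return means, covs


def fit_cross_sectional(data, atlas: SimplexAtlas, opts: FitOptions = None):
    """Coordinate-ascent fit of mesh positions and intensity parameters.

    Returns a :class:`FitResult` with a monotone objective trace.  The same
    routine serves the per-time-point updates of the longitudinal model via
    ``opts.anchor`` (latent mesh), ``opts.prototypes`` and ``opts.P0``.
    """
    opts = opts or FitOptions()
    basis_order = opts.bias_order
    if basis_order is None:
        basis_order = (2,) * len(atlas.grid_shape)
    basis = inten.make_bias_basis(atlas.grid_shape, data.mask, basis_order)
    cache = MembershipCache(atlas)

    anchor = atlas.ref_positions if opts.anchor is None else \
        atlas.check_positions(opts.anchor)
    stiffness = atlas.stiffness if opts.stiffness is None else opts.stiffness
    x = anchor.copy() if opts.init_mesh is None else \
        atlas.check_positions(opts.init_mesh).copy()

    if opts.init_model is None:
        model = _init_model(data, atlas, cache, basis, opts)
    else:
        model = opts.init_model.copy()
    if opts.constraint is not None:
        model = opts.constraint(model)

    trace = []
    converged = False
    n_iter = 0
    for n_iter in range(1, opts.max_outer + 1):
        prior_aligned = _aligned_prior(x, atlas, cache, data)
        for _ in range(opts.n_em):
            model = _em_step(data, model, basis, prior_aligned, opts)
            if opts.constraint is not None:
                model = opts.constraint(model)
        x = optimize_mesh(data, atlas, x, anchor, stiffness, model, basis,
                          opts, cache=cache)
        prior_aligned = _aligned_prior(x, atlas, cache, data)
        obj = _objective(data, model, basis, prior_aligned, x, anchor, atlas,
                         stiffness, opts.prototypes, opts.P0)
        trace.append(obj)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(obj - prev) <= opts.tol * (abs(prev) + 1e-12):
                converged = True
                break
    return FitResult(mesh=x, intensity=model, objective_trace=trace,
                     converged=converged, n_iterations=n_iter, basis=basis)


def segment(data, atlas: SimplexAtlas, x, intensity_model, basis) -> LabelMap:
    """MAP labeling: per-voxel argmax of the class posteriors, ties broken
    toward the lowest class index."""
    prior = meshmod.rasterize_label_prior(x, atlas)
    resp = inten.compute_responsibilities(data, intensity_model, basis, prior)
    labels = np.full(atlas.grid_shape, -1, dtype=np.int32)
    labels.ravel()[data.flat_indices] = np.argmax(resp.weights, axis=1)
    return LabelMap(labels=labels, class_names=list(atlas.class_names),
                    mask=data.mask)


def structure_volumes(labels: LabelMap, voxel_size) -> pd.Series:
    """Per-class volumes in milliliters (voxel sizes in millimeters)."""
    voxel_size = np.asarray(voxel_size, dtype=float)
    vox_ml = float(np.prod(voxel_size)) / 1000.0
    K = len(labels.class_names)
    sel = labels.labels[labels.labels >= 0]
    counts = np.bincount(sel.ravel(), minlength=K)[:K]
    return pd.Series(counts * vox_ml, index=list(labels.class_names),
                     name="volume_ml")
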