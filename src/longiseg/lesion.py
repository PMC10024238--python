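"""White-matter-lesion extension: an extra, temporally uncoupled Gaussian.

Lesions are added to the model as one extra class whose spatial prior is the
white-matter prior scaled by a small mixing weight (lesions can only occur
where white matter is plausible) and whose Gaussian is constrained to be
hyperintense in a designated contrast (e.g. FLAIR) relative to the
white-matter class, enforced by projection after every update.

Because lesion load and shape can change drastically between sessions, the
lesion Gaussian is deliberately *excluded* from the temporal coupling: its
NIW strength is zero at every time point, so its parameters are estimated
independently per scan while all other structures remain coupled through
the subject-specific latents.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from . import intensity as inten
from . import mesh as meshmod
from .cross_sectional import (FitOptions, _init_model, fit_cross_sectional,
                              segment)
from .longitudinal import (LongFitResult, LongHyperparams, build_template,
                           derive_hyperparameters, fit_longitudinal)
from .mesh import MembershipCache, SimplexAtlas

__all__ = [
    "LesionOptions",
    "LesionModel",
    "augment_atlas",
    "binarize_lesion",
    "fit_with_lesion",
]

LESION_CLASS_NAME = "lesion"


@dataclasses.dataclass
class LesionOptions:
    """Configuration of the lesion class.

    ``mixing`` is the prior probability mass diverted from white matter to
    the lesion class; ``init_offset_sd`` is the initial hyperintensity of the
    lesion Gaussian (in units of the white-matter SD in the lesion-visible
    contrast), which breaks the symmetry between the two classes at start-up.
    """

    contrast: int = -1
    mixing: float = 0.05
    threshold: float = 0.5
    reference_class: str = "wm"
    init_offset_sd: float = 3.0
    # minimum connected-component size (voxels); isolated supra-threshold
    # voxels are noise, not lesions — the shape regularization the full
    # lesion model provides is reduced here to this standard size filter
    min_component_voxels: int = 5


@dataclasses.dataclass
class LesionModel:
    """Fitted per-time-point lesion Gaussians and the shared location prior."""

    lesion_means: list  # per time point (N,)
    lesion_covs: list  # per time point (N, N)
    location_prior: np.ndarray  # lesion prior probability per node
    contrast: int
    reference_class: str


def augment_atlas(atlas: SimplexAtlas, mixing, reference_class="wm"
                  ) -> SimplexAtlas:
    """Return an atlas with one extra lesion class.

    The lesion node probability is ``mixing`` times the reference (white
    matter) class probability; rows are renormalized.  ``mixing = 0`` yields
    a lesion class with identically zero prior, which reproduces the
    lesion-free model's behavior exactly.
    """
    if mixing < 0:
        raise ValueError("mixing must be nonnegative")
    if reference_class not in atlas.class_names:
        raise ValueError(f"atlas has no {reference_class!r} class")
    ref_idx = atlas.class_names.index(reference_class)
    p_ref = atlas.node_label_probs[:, ref_idx]
    probs = np.concatenate(
        [atlas.node_label_probs, (mixing * p_ref)[:, None]], axis=1)
    if mixing > 0:  # mixing 0 keeps the original probabilities bit-exact
        probs = probs / probs.sum(axis=1, keepdims=True)
    return SimplexAtlas(
        ref_positions=atlas.ref_positions.copy(),
        simplices=atlas.simplices.copy(),
        node_label_probs=probs,
        stiffness=atlas.stiffness,
        grid_shape=atlas.grid_shape,
        class_names=list(atlas.class_names) + [LESION_CLASS_NAME],
    )


def _hyperintensity_projection(ref_idx, lesion_idx, contrast):
    """Constraint callback applied after every intensity update.

    Clips the lesion mean to stay at or above the reference-class mean in
    the designated contrast, and floors the lesion covariance at the
    reference-class covariance (in the Loewner order): lesion tissue is at
    least as heterogeneous as normal-appearing white matter, which prevents
    the lesion Gaussian from collapsing onto the bright tail of the
    white-matter intensity distribution when no lesions are present.
    """

    def project(model):
        lo = model.means[ref_idx, contrast]
        if model.means[lesion_idx, contrast] < lo:
            model.means[lesion_idx, contrast] = lo
        ref_cov = model.covariances[ref_idx]
        les_cov = model.covariances[lesion_idx]
        L = np.linalg.cholesky(ref_cov)
        Linv = np.linalg.inv(L)
        M = Linv @ les_cov @ Linv.T
        w, V = np.linalg.eigh((M + M.T) / 2.0)
        if np.any(w < 1.0):
            M_floored = (V * np.maximum(w, 1.0)) @ V.T
            floored = L @ M_floored @ L.T
            model.covariances[lesion_idx] = (floored + floored.T) / 2.0
        return model

    return project


def binarize_lesion(responsibilities, lesion_class_index, threshold=0.5):
    """Binary lesion mask from posterior responsibilities (I-vector)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    w = responsibilities.weights if hasattr(responsibilities, "weights") \
        else np.asarray(responsibilities)
    return w[:, lesion_class_index] > threshold


def _filter_small_components(mask_grid, min_voxels):
    """Drop connected lesion components smaller than ``min_voxels``."""
    if min_voxels <= 1 or not mask_grid.any():
        return mask_grid
    labeled, n = ndimage.label(mask_grid)
    if n == 0:
        return mask_grid
    sizes = np.bincount(labeled.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return keep[labeled]


def fit_with_lesion(images, atlas: SimplexAtlas, hyper="auto",
                    lesion_opts: LesionOptions = None,
                    opts: FitOptions = None, template_fit=None):
    """Longitudinal fit with the extra lesion class.

    Runs the standard longitudinal pipeline on the lesion-augmented atlas
    with the lesion class's NIW strength pinned to zero — its Gaussian is
    re-estimated independently at every time point while all anatomical
    classes stay coupled through the subject latents.  Returns
    ``(LongFitResult, lesion_masks, LesionModel)`` where the masks are
    boolean grids (posterior lesion responsibility above the threshold).
    """
    lo = lesion_opts or LesionOptions()
    opts = opts or FitOptions()
    n_contrasts = images[0].n_contrasts
    contrast = lo.contrast % n_contrasts
    aug = augment_atlas(atlas, lo.mixing, lo.reference_class)
    ref_idx = aug.class_names.index(lo.reference_class)
    lesion_idx = aug.n_classes - 1
    constraint = _hyperintensity_projection(ref_idx, lesion_idx, contrast)

    # template fit with a symmetry-broken lesion initialization
    template = build_template(images)
    basis_order = opts.bias_order or (2,) * len(aug.grid_shape)
    basis = inten.make_bias_basis(aug.grid_shape, template.mask, basis_order)
    cache = MembershipCache(aug)
    probe_opts = dataclasses.replace(opts, constraint=None, P0=None,
                                     prototypes=None,
                                     on_degenerate="freeze")
    init_model = _init_model(template, aug, cache, basis, probe_opts)
    wm_sd = np.sqrt(init_model.covariances[ref_idx, contrast, contrast])
    init_model.means[lesion_idx] = init_model.means[ref_idx]
    init_model.covariances[lesion_idx] = init_model.covariances[ref_idx]
    init_model.means[lesion_idx, contrast] += lo.init_offset_sd * wm_sd

    if lo.mixing > 0:
        brighter = template.log_intensities[:, contrast] > \
            init_model.means[ref_idx, contrast]
        if not np.any(brighter):
            raise ValueError(
                "no voxels brighter than the reference class in the "
                "lesion-visible contrast at initialization")

    fit_opts = dataclasses.replace(opts, constraint=constraint,
                                   init_model=init_model,
                                   on_degenerate="freeze")
    if template_fit is None:
        template_fit = fit_cross_sectional(template, aug, fit_opts)

    if isinstance(hyper, str):
        template_labels = segment(template, aug, template_fit.mesh,
                                  template_fit.intensity, template_fit.basis)
        hyper = derive_hyperparameters(template_labels, aug)
    else:
        if hyper.P0.size == atlas.n_classes:
            hyper = LongHyperparams(K0=hyper.K0,
                                    P0=np.append(hyper.P0, 0.0))
    P0 = hyper.P0.copy()
    P0[lesion_idx] = 0.0  # lesions are never coupled across time
    hyper = LongHyperparams(K0=hyper.K0, P0=P0)

    result = fit_longitudinal(images, aug, hyper=hyper, opts=fit_opts,
                              template_fit=template_fit)

    masks, les_means, les_covs = [], [], []
    for t, im in enumerate(images):
        fit = result.timepoint_fits[t]
        prior = meshmod.rasterize_label_prior(fit.mesh, aug)
        resp = inten.compute_responsibilities(im, fit.intensity, fit.basis,
                                              prior)
        flat = binarize_lesion(resp, lesion_idx, lo.threshold)
        grid = np.zeros(aug.grid_shape, dtype=bool)
        grid.ravel()[im.flat_indices] = flat
        masks.append(_filter_small_components(grid, lo.min_component_voxels))
        les_means.append(fit.intensity.means[lesion_idx].copy())
        les_covs.append(fit.intensity.covariances[lesion_idx].copy())

    lesion_model = LesionModel(
        lesion_means=les_means, lesion_covs=les_covs,
        location_prior=aug.node_label_probs[:, lesion_idx].copy(),
        contrast=contrast, reference_class=lo.reference_class)
    return result, masks, lesion_model
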