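"""Synthetic longitudinal phantoms sampled from the generative model itself.

A phantom subject is drawn exactly the way the segmentation model assumes
data arise: a smooth subject-specific deformation of the atlas mesh, a
per-time-point deformation realizing prescribed per-structure volume-change
rates, hard labels from the deformed label prior, and per-class Gaussian
intensity draws plus a smooth additive bias field in the log domain.
Optionally, hyperintense lesion blobs are inserted into the white matter.

Volume-change rates are in percent per year on a *linear* trajectory
(v(t) = v(0) * (1 + rate * t / 100)), so the annualized-percent-change
statistic of an exactly recovered phantom equals the prescribed rate.

What the generator does not emulate: scanner point-spread, motion, Rician
noise, partial-volume mixing, or misregistration — inputs are perfectly
aligned by construction, matching the pipeline's preprocessing contract.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import mesh as meshmod
from .intensity import ImageData, make_bias_basis
from .mesh import SimplexAtlas

__all__ = [
    "PhantomSpec",
    "LesionInsertSpec",
    "PhantomTruth",
    "default_class_means",
    "default_class_covs",
    "simulate_subject",
    "simulate_cohort",
]

# log-domain class mean defaults [background, (rings...), innermost]
_MEANS_BY_K = {
    2: {1: [3.0, 4.6], 2: [[3.0, 3.0], [4.6, 4.2]]},
    3: {1: [3.0, 4.6, 3.6], 2: [[3.0, 3.0], [4.6, 4.2], [3.6, 3.4]]},
    4: {1: [3.0, 4.2, 4.8, 3.6],
        2: [[3.0, 3.0], [4.2, 4.6], [4.8, 4.2], [3.6, 3.4]]},
    5: {1: [3.0, 4.2, 4.8, 4.4, 3.6],
        2: [[3.0, 3.0], [4.2, 4.6], [4.8, 4.2], [4.4, 4.4], [3.6, 3.4]]},
}
_NOISE_SD = 0.1
_CONTRAST_CORR = 0.3


def default_class_means(k_classes, n_contrasts):
    if n_contrasts > 2:
        raise ValueError("defaults cover at most 2 contrasts")
    m = np.asarray(_MEANS_BY_K[k_classes][n_contrasts], dtype=float)
    return m.reshape(k_classes, n_contrasts)


def default_class_covs(k_classes, n_contrasts, noise_sd=_NOISE_SD):
    base = np.full((n_contrasts, n_contrasts), _CONTRAST_CORR)
    np.fill_diagonal(base, 1.0)
    return np.tile(noise_sd**2 * base, (k_classes, 1, 1))


@dataclasses.dataclass
class LesionInsertSpec:
    """Hyperintense blobs inserted into the white-matter region."""

    count: int = 2
    radius: float = 3.0
    contrast: int = -1  # contrast in which lesions are hyperintense
    offset_sd: float = 4.0  # lesion mean offset, in units of the noise SD


@dataclasses.dataclass
class PhantomSpec:
    grid_shape: tuple = (96, 96)
    k_classes: int = 4
    stiffness: float = 0.1
    node_spacing: float = None  # default 6 (2D) / 8 (3D)
    times: tuple = (0.0, 1.0)
    rates: dict = dataclasses.field(default_factory=dict)  # class -> %/yr
    n_contrasts: int = 1
    means: np.ndarray = None
    covs: np.ndarray = None
    bias_amplitude: float = 0.1
    bias_order: tuple = None  # default 2 per dimension
    deform_amplitude: float = 1.0  # voxels
    lesions: Optional[LesionInsertSpec] = None
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.times = tuple(float(t) for t in self.times)
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if self.node_spacing is None:
            self.node_spacing = 6.0
        if self.bias_order is None:
            self.bias_order = (2,) * len(self.grid_shape)
        if self.means is None:
            self.means = default_class_means(self.k_classes, self.n_contrasts)
        self.means = np.asarray(self.means, dtype=float)
        if self.covs is None:
            self.covs = default_class_covs(self.k_classes, self.n_contrasts)
        self.covs = np.asarray(self.covs, dtype=float)

    def make_atlas(self) -> SimplexAtlas:
        return meshmod.make_toy_atlas(
            self.grid_shape, self.k_classes, stiffness=self.stiffness,
            node_spacing=self.node_spacing)


@dataclasses.dataclass
class PhantomTruth:
    atlas: SimplexAtlas
    labels: list  # per-time-point label grids
    volumes: pd.DataFrame  # structures x time points from label counts, ml
    soft_volumes: pd.DataFrame  # expected volumes under the deformed prior
    x0: np.ndarray
    xt: list
    bias_fields: list  # per-time-point (I, N)
    lesion_masks: list  # per-time-point boolean grids (or None)
    spec: PhantomSpec


def _node_lattice_shape(atlas: SimplexAtlas):
    axes = [np.unique(np.round(atlas.ref_positions[:, d], 9))
            for d in range(atlas.ndim)]
    shape = tuple(len(a) for a in axes)
    assert int(np.prod(shape)) == atlas.n_nodes
    return shape


def _smooth_node_field(atlas, rng, amplitude):
    """Smooth random node displacements; shrinks until unfolded."""
    shape = _node_lattice_shape(atlas)
    raw = rng.standard_normal(shape + (atlas.ndim,))
    smooth = np.stack(
        [gaussian_filter(raw[..., d], sigma=1.0, mode="nearest")
         for d in range(atlas.ndim)], axis=-1)
    rms = np.sqrt(np.mean(smooth**2))
    disp = (smooth / max(rms, 1e-12)).reshape(-1, atlas.ndim) * amplitude
    # taper to zero at the mesh boundary so grid coverage is preserved
    ref = atlas.ref_positions
    lo, hi = ref.min(axis=0), ref.max(axis=0)
    edge_dist = np.minimum(ref - lo, hi - ref).min(axis=1)
    span = max(2.0 * (hi - lo).min() / max(len(np.unique(ref[:, 0])) - 1, 1),
               1e-6)
    disp *= np.clip(edge_dist / span, 0.0, 1.0)[:, None]
    x = ref + disp
    for _ in range(20):
        if np.all(meshmod.signed_volumes(x, atlas.simplices) > 0):
            return x
        disp *= 0.7
        x = atlas.ref_positions + disp
    raise RuntimeError("could not produce an unfolded subject deformation")


def _ring_factors(spec: PhantomSpec, atlas: SimplexAtlas, t: float):
    """Per-ring volume factors (inner structure first) at time t, and which
    rings carry an explicit prescription."""
    names = atlas.class_names
    # class order inner -> outer is last class .. class 1
    ring_classes = list(range(spec.k_classes - 1, 0, -1))
    rate_by_class = {}
    for key, val in spec.rates.items():
        idx = names.index(key) if isinstance(key, str) else int(key)
        if idx == 0:
            raise ValueError("cannot prescribe a rate on the background")
        if idx not in ring_classes:
            raise ValueError(f"unknown structure {key!r}")
        rate_by_class[idx] = float(val)
    factors, prescribed = [], []
    for cls in ring_classes:
        rate = rate_by_class.get(cls, 0.0)
        f = 1.0 + rate * t / 100.0
        if f <= 0.05:
            raise ValueError(
                f"rate {rate}%/yr collapses structure {names[cls]} by t={t}")
        factors.append(f)
        prescribed.append(cls in rate_by_class)
    return ring_classes, factors, prescribed


def _radial_warp(positions, center, knots_src, knots_dst, r_edge):
    """Piecewise-linear radial map through the given knots, identity at and
    beyond ``r_edge``."""
    rel = positions - center
    r = np.linalg.norm(rel, axis=1)
    src = np.concatenate([[0.0], knots_src, [r_edge]])
    dst = np.concatenate([[0.0], knots_dst, [r_edge]])
    new_r = np.where(r >= r_edge, r, np.interp(r, src, dst))
    scale = np.where(r > 1e-12, new_r / np.maximum(r, 1e-12), 1.0)
    return center + rel * scale[:, None]


def _warp_for_time(spec, atlas, x0, t):
    """Node positions at time t realizing the prescribed volume factors.

    The map is a *pure scaling* throughout a band of half-width
    ``node_spacing + 2`` voxels around every boundary of a prescribed
    structure.  Pure scalings are affine, so the simplex mesh reproduces
    them exactly inside the band and the labeled region's volume changes by
    exactly the prescribed factor (up to voxel discretization).  The
    transition segments — where the map is merely piecewise linear in the
    radius — are confined to rings without an explicit prescription, whose
    volumes absorb the compensating deformation (as surrounding tissue does
    in real atrophy).
    """
    D = atlas.ndim
    boundaries = np.asarray(
        meshmod.concentric_radii(spec.grid_shape, spec.k_classes))
    ring_classes, factors, prescribed = _ring_factors(spec, atlas, t)
    new_b = np.empty_like(boundaries)
    prev_ref_pow = 0.0
    prev_new_pow = 0.0
    for j, f in enumerate(factors):
        ref_pow = boundaries[j] ** D
        new_pow = prev_new_pow + f * (ref_pow - prev_ref_pow)
        new_b[j] = new_pow ** (1.0 / D)
        prev_ref_pow, prev_new_pow = ref_pow, new_pow
    if np.any(np.diff(np.concatenate([[0.0], new_b])) <= 0):
        raise ValueError("prescribed rates collapse a ring within the series")
    center = (np.asarray(spec.grid_shape, dtype=float) - 1.0) / 2.0
    r_edge = float(min(spec.grid_shape)) / 2.0
    if new_b[-1] >= r_edge:
        raise ValueError("prescribed growth exceeds the grid")

    # boundaries needing an exact (pure-scale) band: those touching a
    # prescribed ring (ring j is bounded by boundaries j-1 and j)
    banded = sorted({
        b_idx
        for j, is_presc in enumerate(prescribed) if is_presc
        for b_idx in ([j] if j == 0 else [j - 1, j])
    })
    if not banded:
        return x0.copy()
    # the band must cover the structure's full (truncated) prior support
    # plus one layer of simplices, so every simplex carrying prior mass of
    # the structure deforms by the exact affine scaling
    support = meshmod.TOY_BOUNDARY_SOFTNESS * np.log(1.0 / meshmod.TOY_PROB_FLOOR)
    half = support + spec.node_spacing + 3.0
    knots_src, knots_dst = [], []
    for b_idx in banded:
        b, nb = boundaries[b_idx], new_b[b_idx]
        s = nb / b
        lo, hi = max(b - half, 0.0), min(b + half, r_edge)
        if lo <= half / 4:  # band reaches the center: scale from r = 0
            lo = 0.0
        knots_src.extend([lo, hi])
        knots_dst.extend([s * lo, s * hi])
    knots_src = np.asarray(knots_src)
    knots_dst = np.asarray(knots_dst)
    keep = np.concatenate([[True], np.diff(knots_src) > 1e-9])
    knots_src, knots_dst = knots_src[keep], knots_dst[keep]
    if np.any(np.diff(knots_src) <= 0) or np.any(np.diff(knots_dst) <= 0) \
            or knots_dst[-1] >= r_edge:
        raise ValueError(
            "prescribed structures too close together for an exact warp; "
            "use a larger grid or smaller node spacing")
    return _radial_warp(x0, center, knots_src, knots_dst, r_edge)


def _insert_lesions(spec, rng, labels, wm_class, grid_shape):
    les = spec.lesions
    D = len(grid_shape)
    coords = np.stack(np.nonzero(labels == wm_class), axis=1)
    if coords.shape[0] == 0:
        raise ValueError("no white-matter voxels to host lesions")
    grids = np.stack(np.meshgrid(*[np.arange(s) for s in grid_shape],
                                 indexing="ij"), axis=-1)
    mask = np.zeros(grid_shape, dtype=bool)
    placed = 0
    for _ in range(200):
        if placed == les.count:
            break
        c = coords[rng.integers(coords.shape[0])]
        dist2 = np.sum((grids - c) ** 2, axis=-1)
        blob = dist2 <= les.radius**2
        if np.all(labels[blob] == wm_class) and not np.any(mask & blob):
            mask |= blob
            placed += 1
    if placed < les.count:
        raise RuntimeError("could not place the requested lesion count")
    return mask


def simulate_subject(spec: PhantomSpec):
    """Sample one longitudinal subject; returns ``(images, truth)``.

    Deterministic for a fixed spec (including its seed).
    """
    atlas = spec.make_atlas()
    rng = np.random.default_rng(spec.seed)
    x0 = _smooth_node_field(atlas, rng, spec.deform_amplitude) \
        if spec.deform_amplitude > 0 else atlas.ref_positions.copy()

    grid_shape = spec.grid_shape
    mask = np.ones(grid_shape, dtype=bool)
    n_vox = int(np.prod(grid_shape))
    basis = make_bias_basis(grid_shape, mask, spec.bias_order)
    K, N = spec.k_classes, spec.n_contrasts
    chol = np.linalg.cholesky(spec.covs)
    wm_class = atlas.class_names.index("wm") if "wm" in atlas.class_names \
        else None

    images, labels_list, vols, soft_vols, xts = [], [], [], [], []
    bias_list, lesion_list = [], []
    vox_ml = 1.0 / 1000.0  # 1 mm^3 voxels
    for t in spec.times:
        xt = _warp_for_time(spec, atlas, x0, t)
        if np.any(meshmod.signed_volumes(xt, atlas.simplices) <= 0):
            raise ValueError(f"deformation folds the mesh at t={t}")
        prior = meshmod.rasterize_label_prior(xt, atlas)
        if prior.probs.shape[0] != n_vox:
            raise RuntimeError("toy mesh does not cover the grid")
        labels = np.argmax(prior.probs, axis=1).reshape(grid_shape)
        noise = rng.standard_normal((n_vox, N))
        flat_labels = labels.ravel()
        vals = spec.means[flat_labels] + np.einsum(
            "inm,im->in", chol[flat_labels], noise)
        coeffs = rng.normal(0.0, spec.bias_amplitude / 2.0,
                            (N, basis.n_funcs))
        bias = basis.values @ coeffs.T if spec.bias_amplitude > 0 else \
            np.zeros((n_vox, N))
        vals = vals + bias

        lesion_mask = None
        if spec.lesions is not None:
            if wm_class is None:
                raise ValueError("lesion insertion needs a 'wm' class")
            lesion_mask = _insert_lesions(spec, rng, labels, wm_class,
                                          grid_shape)
            les = spec.lesions
            offset = np.zeros(N)
            offset[les.contrast % N] = les.offset_sd * np.sqrt(
                spec.covs[wm_class, les.contrast % N, les.contrast % N])
            sel = lesion_mask.ravel()
            les_noise = rng.standard_normal((int(sel.sum()), N))
            vals[sel] = (spec.means[wm_class] + offset
                         + les_noise @ chol[wm_class].T + bias[sel])

        images.append(ImageData(log_intensities=vals, mask=mask,
                                grid_shape=grid_shape,
                                voxel_size=(1.0,) * len(grid_shape),
                                timepoint_time=t))
        labels_list.append(labels)
        vols.append(np.bincount(flat_labels, minlength=K)[:K] * vox_ml)
        soft_vols.append(prior.probs.sum(axis=0) * vox_ml)
        xts.append(xt)
        bias_list.append(bias)
        lesion_list.append(lesion_mask)

    cols = [f"t{j}" for j in range(len(spec.times))]
    volumes = pd.DataFrame(np.stack(vols, axis=1),
                           index=list(atlas.class_names), columns=cols)
    soft_volumes = pd.DataFrame(np.stack(soft_vols, axis=1),
                                index=list(atlas.class_names), columns=cols)
    truth = PhantomTruth(atlas=atlas, labels=labels_list, volumes=volumes,
                         soft_volumes=soft_volumes, x0=x0, xt=xts,
                         bias_fields=bias_list, lesion_masks=lesion_list,
                         spec=spec)
    return images, truth


@dataclasses.dataclass
class Cohort:
    manifest: pd.DataFrame
    subjects: list  # list of (images, truth)
    true_apcs: pd.DataFrame  # per subject: group + prescribed rates


def simulate_cohort(n_per_group, group_rate_specs, spec_template: PhantomSpec,
                    seed=0) -> Cohort:
    """Simulate two (or more) groups of independent subjects.

    ``group_rate_specs`` maps group name -> {structure: (mean_rate, sd)} in
    percent per year; each subject draws its rates from those normals.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    rows, subjects, apc_rows = [], [], []
    sid = 0
    for group, rate_spec in group_rate_specs.items():
        for _ in range(n_per_group):
            rates = {}
            for struct, (mean_rate, sd) in rate_spec.items():
                rates[struct] = float(rng.normal(mean_rate, sd))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            spec = dataclasses.replace(spec_template, rates=rates,
                                       seed=sub_seed)
            images, truth = simulate_subject(spec)
            subjects.append((images, truth))
            for j, t in enumerate(spec.times):
                rows.append(dict(subject=sid, group=group, timepoint=j,
                                 time_years=t))
            apc_rows.append(dict(subject=sid, group=group, **rates))
            sid += 1
    return Cohort(manifest=pd.DataFrame(rows), subjects=subjects,
                  true_apcs=pd.DataFrame(apc_rows))
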