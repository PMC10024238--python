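"""Gaussian intensity likelihood with smooth additive bias field.

Each of the K anatomical classes has a multivariate Gaussian over the
log-transformed multi-contrast intensities d_i.  A smooth bias artifact,
additive in the log domain, is modeled per contrast as a linear combination
of separable cosine basis functions:

    p(d_i | l_i = k) = N(d_i | mu_k + C phi_i, Sigma_k)

where phi_i stacks the P basis functions at voxel i and row n of C holds the
bias coefficients of contrast n.  Estimation updates are provided both for
the plain EM (maximum-likelihood) case and for the maximum-a-posteriori case
in which (mu_k, Sigma_k) carry a normal-inverse-Wishart prior centered on
subject-specific prototypes — the coupling that makes longitudinal fits
temporally consistent.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
from scipy.special import logsumexp, multigammaln

from .mesh import LabelPriorField

__all__ = [
    "ImageData",
    "BiasBasis",
    "IntensityModel",
    "Responsibilities",
    "log_transform",
    "make_bias_basis",
    "class_log_likelihoods",
    "compute_responsibilities",
    "update_gaussians",
    "update_bias",
    "log_evidence",
    "niw_logpdf",
    "prior_on_mask",
    "DegenerateClassError",
]


class DegenerateClassError(RuntimeError):
    pass


@dataclasses.dataclass
class ImageData:
    """Masked multi-contrast log-intensities on a voxel grid.

    ``log_intensities`` is (I, N): one row per analyzed (masked) voxel in
    C-order scan of the grid, one column per MRI contrast.
    """

    log_intensities: np.ndarray
    mask: np.ndarray
    grid_shape: tuple
    voxel_size: tuple = None
    timepoint_time: float = 0.0
    log_floor: float = None

    def __post_init__(self):
        self.log_intensities = np.atleast_2d(
            np.asarray(self.log_intensities, dtype=float)
        )
        self.mask = np.asarray(self.mask, dtype=bool)
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if self.voxel_size is None:
            self.voxel_size = (1.0,) * len(self.grid_shape)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.mask.shape != self.grid_shape:
            raise ValueError("mask shape must equal grid_shape")
        n_masked = int(self.mask.sum())
        if n_masked == 0:
            raise ValueError("mask selects no voxels")
        if self.log_intensities.shape[0] != n_masked:
            raise ValueError(
                f"log_intensities rows ({self.log_intensities.shape[0]}) must "
                f"match masked voxel count ({n_masked})"
            )
        if not np.all(np.isfinite(self.log_intensities)):
            raise ValueError("masked log-intensities must be finite")

    @property
    def n_voxels(self) -> int:
        return self.log_intensities.shape[0]

    @property
    def n_contrasts(self) -> int:
        return self.log_intensities.shape[1]

    @property
    def flat_indices(self) -> np.ndarray:
        return np.nonzero(self.mask.ravel())[0]


def log_transform(raw_intensities, mask, floor=None) -> ImageData:
    """Natural log of the raw intensities on the mask, with a small positive
    floor so zero-valued voxels stay finite.

    ``floor`` defaults to 1e-4 of the maximum masked intensity.
    """
    raw = np.asarray(raw_intensities, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    grid_shape = mask.shape
    if raw.shape[: mask.ndim] != grid_shape:
        raise ValueError("raw volume and mask shapes disagree")
    if raw.ndim == mask.ndim:
        raw = raw[..., None]
    vals = raw[mask]  # (I, N)
    if np.any(vals < 0):
        raise ValueError("raw intensities must be nonnegative on the mask")
    vmax = vals.max()
    if vmax == 0:
        raise ValueError("all masked intensities are zero")
    if floor is None:
        floor = 1e-4 * vmax
    return ImageData(
        log_intensities=np.log(np.maximum(vals, floor)),
        mask=mask,
        grid_shape=grid_shape,
        log_floor=float(floor),
    )


@dataclasses.dataclass
class BiasBasis:
    """Separable cosine (DCT-II style) bias basis evaluated at masked voxels.

    The first column is constant, so global intensity scaling differences are
    absorbed by the bias model; all columns are bounded in [-1, 1].
    """

    values: np.ndarray  # (I, P)
    order: tuple

    @property
    def n_funcs(self) -> int:
        return self.values.shape[1]


def make_bias_basis(grid_shape, mask, order) -> BiasBasis:
    grid_shape = tuple(int(s) for s in grid_shape)
    if np.isscalar(order):
        order = (int(order),) * len(grid_shape)
    order = tuple(int(o) for o in order)
    if any(o < 0 for o in order):
        raise ValueError("basis order must be nonnegative")
    mask = np.asarray(mask, dtype=bool)
    coords = np.nonzero(mask)
    axis_funcs = []
    for d, (s, o) in enumerate(zip(grid_shape, order)):
        u = (coords[d] + 0.5) / s  # voxel centers mapped to (0, 1)
        axis_funcs.append([np.cos(np.pi * p * u) for p in range(o + 1)])
    cols = []
    for combo in itertools.product(*[range(o + 1) for o in order]):
        col = np.ones(coords[0].shape[0])
        for d, p in enumerate(combo):
            col = col * axis_funcs[d][p]
        cols.append(col)
    values = np.stack(cols, axis=1)
    return BiasBasis(values=values, order=order)


@dataclasses.dataclass
class IntensityModel:
    """Per-class Gaussian parameters and bias-field coefficients."""

    means: np.ndarray  # (K, N)
    covariances: np.ndarray  # (K, N, N)
    bias_coeffs: np.ndarray  # (N, P)
    class_names: list = None

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[..., None, None] * 0 + self.covariances
        self.bias_coeffs = np.atleast_2d(np.asarray(self.bias_coeffs, dtype=float))
        K, N = self.means.shape
        if self.covariances.shape != (K, N, N):
            raise ValueError("covariances must be (K, N, N)")
        if self.bias_coeffs.shape[0] != N:
            raise ValueError("bias_coeffs must have one row per contrast")
        _assert_spd(self.covariances)

    @property
    def n_classes(self) -> int:
        return self.means.shape[0]

    @property
    def n_contrasts(self) -> int:
        return self.means.shape[1]

    def copy(self) -> "IntensityModel":
        return IntensityModel(
            means=self.means.copy(),
            covariances=self.covariances.copy(),
            bias_coeffs=self.bias_coeffs.copy(),
            class_names=None if self.class_names is None else list(self.class_names),
        )


@dataclasses.dataclass
class Responsibilities:
    weights: np.ndarray  # (I, K)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < -1e-12) or np.any(self.weights > 1 + 1e-12):
            raise ValueError("responsibilities must lie in [0, 1]")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("responsibility rows must sum to 1")


def _assert_spd(covs):
    covs = np.asarray(covs)
    if not np.allclose(covs, np.swapaxes(covs, -1, -2), atol=1e-10):
        raise ValueError("covariance not symmetric")
    eig = np.linalg.eigvalsh(covs)
    if np.any(eig <= 0):
        raise ValueError("covariance not positive definite")


def bias_field(model: IntensityModel, basis: BiasBasis) -> np.ndarray:
    """Bias value at each masked voxel, (I, N)."""
    return basis.values @ model.bias_coeffs.T


def class_log_likelihoods(data: ImageData, model: IntensityModel,
                          basis: BiasBasis) -> np.ndarray:
    """(I, K) matrix of log N(d_i | mu_k + C phi_i, Sigma_k)."""
    _assert_spd(model.covariances)
    resid = data.log_intensities - bias_field(model, basis)  # (I, N)
    I, N = resid.shape
    K = model.n_classes
    out = np.empty((I, K))
    for k in range(K):
        L = np.linalg.cholesky(model.covariances[k])
        e = resid - model.means[k]
        z = np.linalg.solve(L, e.T)  # use L: solve triangular via generic
        maha = np.sum(z**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, k] = -0.5 * (N * np.log(2 * np.pi) + logdet + maha)
    return out


def prior_on_mask(prior: LabelPriorField, data: ImageData) -> np.ndarray:
    """Align a rasterized label prior with the data's masked voxels.

    Masked voxels not covered by the mesh are an error: the caller should
    restrict the mask to the mesh support first.
    """
    flat = data.flat_indices
    pos = np.searchsorted(prior.voxel_index_map, flat)
    ok = (pos < prior.voxel_index_map.size) & (
        prior.voxel_index_map[np.minimum(pos, prior.voxel_index_map.size - 1)]
        == flat
    )
    if not np.all(ok):
        raise ValueError(
            f"{int((~ok).sum())} masked voxels lie outside the mesh support"
        )
    return prior.probs[pos]


def compute_responsibilities(data: ImageData, model: IntensityModel,
                             basis: BiasBasis, prior) -> Responsibilities:
    """Per-voxel posterior class probabilities (log-domain normalization).

    ``prior`` may be a :class:`LabelPriorField` or an (I, K) array aligned
    with the data rows.
    """
    if isinstance(prior, LabelPriorField):
        prior = prior_on_mask(prior, data)
    prior = np.asarray(prior, dtype=float)
    log_lik = class_log_likelihoods(data, model, basis)
    with np.errstate(divide="ignore"):
        log_post = log_lik + np.log(prior)
    norm = logsumexp(log_post, axis=1)
    bad = ~np.isfinite(norm)
    if np.any(bad):
        raise ValueError(
            f"all class posteriors vanish at voxel row {int(np.nonzero(bad)[0][0])}"
        )
    return Responsibilities(weights=np.exp(log_post - norm[:, None]))


def log_evidence(data: ImageData, model: IntensityModel, basis: BiasBasis,
                 prior) -> float:
    """Sum over voxels of log sum_k N(d_i | mu_k + C phi_i, Sigma_k) pi_ik —
    the data term of the model log-posterior."""
    if isinstance(prior, LabelPriorField):
        prior = prior_on_mask(prior, data)
    log_lik = class_log_likelihoods(data, model, basis)
    with np.errstate(divide="ignore"):
        return float(logsumexp(log_lik + np.log(prior), axis=1).sum())


def _floor_covariance(cov):
    n = cov.shape[-1]
    w, V = np.linalg.eigh((cov + cov.T) / 2.0)
    floor = 1e-8 * max(np.trace(cov) / n, 1e-300)
    w = np.maximum(w, floor)
    return (V * w) @ V.T


def update_gaussians(data: ImageData, resp: Responsibilities, basis: BiasBasis,
                     bias_coeffs, prototypes=None, P0=None, min_voxels=10):
    """M-step update of the class means and covariances.

    For classes with NIW strength ``P0[k] == 0`` (or no prototypes) this is
    the standard EM weighted mean / covariance of the bias-corrected
    residuals.  For ``P0[k] > 0`` it is the joint posterior mode of
    (mu_k, Sigma_k) under the prior

        N(mu_k | mu0_k, Sigma_k / P0_k) IW(Sigma_k | P0_k Sigma0_k, P0_k - N - 2)

    whose degrees-of-freedom convention makes the MAP estimate coincide with
    the ML one as P0_k -> 0.  Returns ``(means, covariances)``.
    """
    C = np.atleast_2d(np.asarray(bias_coeffs, dtype=float))
    resid = data.log_intensities - basis.values @ C.T
    W = resp.weights
    I, K = W.shape
    N = resid.shape[1]
    if P0 is None:
        P0 = np.zeros(K)
    P0 = np.broadcast_to(np.asarray(P0, dtype=float), (K,)).copy()
    if np.any(P0 > 0) and prototypes is None:
        raise ValueError("prototypes required when any P0[k] > 0")
    improper = (P0 > 0) & (P0 <= 2 * N + 1)
    if np.any(improper):
        warnings.warn(
            "NIW prior is improper for P0 <= 2N+1 for classes "
            f"{np.nonzero(improper)[0].tolist()}; the posterior-mode update "
            "remains defined and is used as is",
            RuntimeWarning,
        )

    R = W.sum(axis=0)  # (K,)
    means = np.empty((K, N))
    covs = np.empty((K, N, N))
    for k in range(K):
        if R[k] < min_voxels and P0[k] == 0:
            raise DegenerateClassError(
                f"class {k} has total responsibility {R[k]:.2f} < "
                f"{min_voxels} and no prior to regularize it"
            )
        xbar = (W[:, k] @ resid) / max(R[k], 1e-300)
        diff = resid - xbar
        S = (W[:, k, None] * diff).T @ diff
        if P0[k] == 0 or prototypes is None:
            means[k] = xbar
            covs[k] = _floor_covariance(S / max(R[k], 1e-300))
        else:
            mu0, Sigma0 = prototypes[0][k], prototypes[1][k]
            kappa = P0[k] + R[k]
            means[k] = (P0[k] * mu0 + R[k] * xbar) / kappa
            dm = xbar - mu0
            Psi = P0[k] * Sigma0 + S + (P0[k] * R[k] / kappa) * np.outer(dm, dm)
            nu_n = (P0[k] - N - 2) + R[k]
            covs[k] = _floor_covariance(Psi / (nu_n + N + 2))
    return means, covs


def update_bias(data: ImageData, resp: Responsibilities, means, covariances,
                basis: BiasBasis) -> np.ndarray:
    """Exact solution of the weighted least-squares normal equations for the
    bias coefficients C, with full-covariance coupling across contrasts.

    Maximizes the expected complete-data log-likelihood
    sum_ik w_ik log N(d_i - C phi_i | mu_k, Sigma_k) over C.
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    covariances = np.asarray(covariances, dtype=float)
    W = resp.weights
    Phi = basis.values  # (I, P)
    I, P = Phi.shape
    K, N = means.shape
    if int((W.sum(axis=1) > 0).sum()) < P:
        raise ValueError("fewer weighted voxels than basis functions")
    Lam = np.linalg.inv(covariances)  # (K, N, N)
    # per-voxel precision weights: w_i^{nn'} = sum_k w_ik Lam_k[n,n']
    Wprec = np.tensordot(W, Lam, axes=(1, 0))  # (I, N, N)
    # rhs target: sum_k w_ik Lam_k (d_i - mu_k)
    t = np.einsum("ik,knm,im->in", W, Lam, data.log_intensities) - np.tensordot(
        W, np.einsum("knm,km->kn", Lam, means), axes=(1, 0)
    )  # (I, N)
    # normal matrix A[(n p), (n' p')] = sum_i w_i^{nn'} phi_ip phi_ip'
    A = np.einsum("inm,ip,iq->npmq", Wprec, Phi, Phi).reshape(N * P, N * P)
    b = np.einsum("in,ip->np", t, Phi).reshape(N * P)
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular bias normal equations; try a lower basis order"
        ) from exc
    return sol.reshape(N, P)


def niw_logpdf(mu, Sigma, mu0, Sigma0, P0, clamp_improper=True) -> float:
    """Log density of the normal-inverse-Wishart coupling prior

    N(mu | mu0, Sigma / P0) IW(Sigma | P0 Sigma0, P0 - N - 2).

    For P0 <= 2N+1 the IW part is improper; with ``clamp_improper`` the
    degrees of freedom are clamped just above the properness bound so that a
    finite (if arbitrary) normalizer exists.
    """
    mu = np.asarray(mu, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    mu0 = np.asarray(mu0, dtype=float)
    Sigma0 = np.asarray(Sigma0, dtype=float)
    N = mu.size
    nu = P0 - N - 2
    if nu <= N - 1:
        if not clamp_improper:
            raise ValueError("improper IW: requires P0 > 2N+1")
        nu = N - 1 + 1e-3
    Psi = P0 * Sigma0
    sign, logdet_S = np.linalg.slogdet(Sigma)
    _, logdet_Psi = np.linalg.slogdet(Psi)
    Sinv = np.linalg.inv(Sigma)
    dm = mu - mu0
    log_n = (
        -0.5 * N * np.log(2 * np.pi)
        + 0.5 * N * np.log(P0)
        - 0.5 * logdet_S
        - 0.5 * P0 * dm @ Sinv @ dm
    )
    log_iw = (
        0.5 * nu * logdet_Psi
        - 0.5 * nu * N * np.log(2.0)
        - multigammaln(0.5 * nu, N)
        - 0.5 * (nu + N + 1) * logdet_S
        - 0.5 * np.trace(Psi @ Sinv)
    )
    return float(log_n + log_iw)
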