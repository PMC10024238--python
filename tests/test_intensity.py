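import math

import numpy as np
import pytest
from scipy.optimize import minimize

from longiseg import intensity as it
from longiseg.intensity import (DegenerateClassError, ImageData,
                                IntensityModel, Responsibilities,
                                class_log_likelihoods,
                                compute_responsibilities, log_transform,
                                make_bias_basis, update_bias,
                                update_gaussians)


def flat_image(values, n_contrasts=1):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != n_contrasts:
        values = values.reshape(-1, n_contrasts)
    n = values.shape[0]
    mask = np.ones((n, 1), dtype=bool)
    return ImageData(log_intensities=values, mask=mask, grid_shape=(n, 1))


def constant_basis(data):
    return make_bias_basis(data.grid_shape, data.mask,
                           (0,) * len(data.grid_shape))


class TestLogTransform:
    def test_natural_log_of_e_is_one(self):
        raw = np.full((2, 2), math.e)
        data = log_transform(raw, np.ones((2, 2), bool))
        np.testing.assert_allclose(data.log_intensities, 1.0)

    def test_floor_applies_to_zeros(self):
        raw = np.array([[0.0, 1.0]])
        data = log_transform(raw, np.ones((1, 2), bool), floor=1e-4)
        assert data.log_intensities[0, 0] == pytest.approx(math.log(1e-4))
        assert data.log_floor == 1e-4

    def test_monotonicity_preserved(self, rng):
        raw = rng.uniform(0.5, 10.0, (5, 5))
        data = log_transform(raw, np.ones((5, 5), bool))
        order_raw = np.argsort(raw.ravel())
        order_log = np.argsort(data.log_intensities[:, 0])
        np.testing.assert_array_equal(order_raw, order_log)

    def test_all_zero_image_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            log_transform(np.zeros((3, 3)), np.ones((3, 3), bool))


class TestBiasBasis:
    def test_zeroth_order_is_single_constant(self):
        basis = make_bias_basis((8, 8), np.ones((8, 8), bool), (0, 0))
        assert basis.n_funcs == 1
        np.testing.assert_allclose(basis.values, 1.0)

    def test_first_order_column_antisymmetric(self):
        mask = np.ones((8, 4), bool)
        basis = make_bias_basis((8, 4), mask, (1, 0))
        assert basis.n_funcs == 2
        col = basis.values[:, 1].reshape(8, 4)
        np.testing.assert_allclose(col, -col[::-1], atol=1e-12)
        assert np.all(np.diff(col[:, 0]) < 0)  # decreasing along the axis

    def test_columns_bounded_by_one(self):
        basis = make_bias_basis((16, 16), np.ones((16, 16), bool), (3, 3))
        assert basis.n_funcs == 16
        assert np.max(np.abs(basis.values)) <= 1.0 + 1e-12


class TestClassLogLikelihoods:
    def test_standard_normal_at_mode(self):
        data = flat_image([0.0])
        model = IntensityModel(means=[[0.0]], covariances=np.array([[[1.0]]]),
                               bias_coeffs=[[0.0]])
        ll = class_log_likelihoods(data, model, constant_basis(data))
        assert ll[0, 0] == pytest.approx(math.log(1 / math.sqrt(2 * math.pi)))

    def test_bias_constant_and_mean_shift_cancel(self, rng):
        vals = rng.normal(2.0, 0.3, (20, 1))
        data = flat_image(vals)
        basis = constant_basis(data)
        model = IntensityModel(means=[[1.8], [2.4]],
                               covariances=np.array([[[0.09]], [[0.09]]]),
                               bias_coeffs=[[0.0]])
        shifted_data = flat_image(vals + 0.7)
        shifted = IntensityModel(means=[[1.8 + 0.7], [2.4 + 0.7]],
                                 covariances=model.covariances,
                                 bias_coeffs=[[0.0]])
        np.testing.assert_allclose(
            class_log_likelihoods(data, model, basis),
            class_log_likelihoods(shifted_data, shifted, basis), atol=1e-10)

    def test_bivariate_hand_evaluated_density(self):
        mu = np.array([1.0, -0.5])
        cov = np.array([[0.5, 0.2], [0.2, 0.8]])
        d = np.array([1.3, 0.1])
        data = flat_image(d, n_contrasts=2)
        model = IntensityModel(means=mu[None], covariances=cov[None],
                               bias_coeffs=np.zeros((2, 1)))
        ll = class_log_likelihoods(data, model, constant_basis(data))
        diff = d - mu
        expected = (-math.log(2 * math.pi)
                    - 0.5 * math.log(np.linalg.det(cov))
                    - 0.5 * diff @ np.linalg.inv(cov) @ diff)
        assert ll[0, 0] == pytest.approx(expected, abs=1e-10)

    def test_non_spd_covariance_rejected(self):
        data = flat_image([0.0])
        with pytest.raises(ValueError, match="positive definite"):
            IntensityModel(means=[[0.0]], covariances=np.array([[[-1.0]]]),
                           bias_coeffs=[[0.0]])


class TestResponsibilities:
    def test_symmetric_classes_uniform_prior(self):
        data = flat_image([0.3, 0.7, -0.2])
        model = IntensityModel(means=[[0.0], [0.0], [0.0]],
                               covariances=np.ones((3, 1, 1)),
                               bias_coeffs=[[0.0]])
        resp = compute_responsibilities(data, model, constant_basis(data),
                                        np.full((3, 3), 1 / 3))
        np.testing.assert_allclose(resp.weights, 1 / 3, atol=1e-12)

    def test_zero_prior_annihilates_class(self):
        data = flat_image([0.0])
        model = IntensityModel(means=[[0.0], [5.0]],
                               covariances=np.ones((2, 1, 1)),
                               bias_coeffs=[[0.0]])
        resp = compute_responsibilities(data, model, constant_basis(data),
                                        np.array([[0.0, 1.0]]))
        assert resp.weights[0, 0] == 0.0
        assert resp.weights[0, 1] == 1.0

    def test_two_class_hand_arithmetic(self):
        data = flat_image([0.5])
        model = IntensityModel(means=[[0.0], [2.0]],
                               covariances=np.ones((2, 1, 1)),
                               bias_coeffs=[[0.0]])
        resp = compute_responsibilities(data, model, constant_basis(data),
                                        np.array([[0.5, 0.5]]))
        d0 = math.exp(-0.5 * 0.25)
        d1 = math.exp(-0.5 * 2.25)
        assert resp.weights[0, 0] == pytest.approx(d0 / (d0 + d1), abs=1e-10)

    def test_all_zero_posterior_names_voxel(self):
        data = flat_image([0.0, 1.0])
        model = IntensityModel(means=[[0.0]], covariances=np.array([[[1.0]]]),
                               bias_coeffs=[[0.0]])
        prior = np.array([[1.0], [0.0]])
        with pytest.raises(ValueError, match="row 1"):
            compute_responsibilities(data, model, constant_basis(data), prior)

    def test_rows_sum_to_one(self, rng):
        vals = rng.normal(0, 1, (30, 1))
        data = flat_image(vals)
        model = IntensityModel(means=[[-1.0], [0.5], [2.0]],
                               covariances=0.5 * np.ones((3, 1, 1)),
                               bias_coeffs=[[0.0]])
        prior = rng.dirichlet([1, 1, 1], 30)
        resp = compute_responsibilities(data, model, constant_basis(data),
                                        prior)
        np.testing.assert_allclose(resp.weights.sum(axis=1), 1.0, atol=1e-9)


class TestUpdateGaussians:
    def test_hard_responsibilities_give_sample_moments(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 15), rng.normal(5, 2, 25)])
        data = flat_image(vals)
        w = np.zeros((40, 2))
        w[:15, 0] = 1.0
        w[15:, 1] = 1.0
        means, covs = update_gaussians(data, Responsibilities(w),
                                       constant_basis(data), [[0.0]])
        assert means[0, 0] == pytest.approx(vals[:15].mean())
        assert means[1, 0] == pytest.approx(vals[15:].mean())
        assert covs[0, 0, 0] == pytest.approx(vals[:15].var())  # biased
        assert covs[1, 0, 0] == pytest.approx(vals[15:].var())

    def test_huge_prior_pins_to_prototypes(self, rng):
        vals = rng.normal(1.0, 0.5, (50, 1))
        data = flat_image(vals)
        w = np.ones((50, 1))
        protos = (np.array([[3.0]]), np.array([[[0.25]]]))
        means, covs = update_gaussians(
            data, Responsibilities(w), constant_basis(data), [[0.0]],
            prototypes=protos, P0=[1e12])
        assert means[0, 0] == pytest.approx(3.0, rel=1e-4)
        assert covs[0, 0, 0] == pytest.approx(0.25, rel=1e-4)

    def test_map_matches_numeric_oracle(self, rng):
        """MAP for one class under the NIW prior vs direct numeric
        maximization of weighted log-likelihood + log-prior."""
        vals = rng.normal(1.0, 0.5, 20)
        w = rng.uniform(0.2, 1.0, 20)
        data = flat_image(vals)
        resp = Responsibilities(np.stack([w, 1 - w], axis=1))
        mu0, s0, P0 = 0.8, 0.3, 5.0
        protos = (np.array([[mu0], [0.0]]), np.array([[[s0]], [[1.0]]]))
        means, covs = update_gaussians(data, resp, constant_basis(data),
                                       [[0.0]], prototypes=protos,
                                       P0=[P0, P0])

        nu0 = P0 - 1 - 2

        def neg(p):
            mu, ls = p
            s2 = math.exp(ls)
            ll = np.sum(w * (-0.5 * np.log(2 * np.pi * s2)
                             - 0.5 * (vals - mu) ** 2 / s2))
            lp = (-0.5 * math.log(s2) - 0.5 * P0 * (mu - mu0) ** 2 / s2
                  - 0.5 * (nu0 + 2) * math.log(s2) - 0.5 * P0 * s0 / s2)
            return -(ll + lp)

        # coarse grid then local refinement
        grid_mu = np.linspace(0.0, 2.0, 81)
        grid_ls = np.linspace(math.log(0.01), math.log(1.0), 81)
        best = min(((neg((m, ls)), m, ls) for m in grid_mu
                    for ls in grid_ls))
        res = minimize(neg, [best[1], best[2]], method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-12))
        assert means[0, 0] == pytest.approx(res.x[0], rel=1e-4)
        assert covs[0, 0, 0] == pytest.approx(math.exp(res.x[1]), rel=1e-4)

    def test_map_continuous_at_zero_prior_strength(self, rng):
        vals = rng.normal(0.0, 1.0, (200, 1))
        data = flat_image(vals)
        w = np.ones((200, 1))
        ml_means, ml_covs = update_gaussians(
            data, Responsibilities(w), constant_basis(data), [[0.0]])
        protos = (np.array([[5.0]]), np.array([[[9.0]]]))
        with pytest.warns(RuntimeWarning, match="improper"):
            map_means, map_covs = update_gaussians(
                data, Responsibilities(w), constant_basis(data), [[0.0]],
                prototypes=protos, P0=[1e-8])
        np.testing.assert_allclose(map_means, ml_means, rtol=1e-6)
        np.testing.assert_allclose(map_covs, ml_covs, rtol=1e-6)

    def test_starved_class_without_prior_raises(self):
        data = flat_image(np.zeros(20))
        w = np.zeros((20, 2))
        w[:, 0] = 0.9
        w[:, 1] = 0.1
        with pytest.raises(DegenerateClassError, match="class 1"):
            update_gaussians(data, Responsibilities(w), constant_basis(data),
                             [[0.0]])


class TestUpdateBias:
    def test_no_bias_data_recovers_zero_coefficients(self, rng):
        # noise-free single-class data with exact responsibilities: all
        # coefficients vanish except the constant absorbing the mean offset
        grid = (16, 16)
        mask = np.ones(grid, bool)
        basis = make_bias_basis(grid, mask, (2, 2))
        vals = np.full((256, 1), 2.3)
        data = ImageData(vals, mask, grid)
        w = np.ones((256, 1))
        C = update_bias(data, Responsibilities(w), [[2.0]],
                        np.array([[[0.01]]]), basis)
        np.testing.assert_allclose(C[0, 1:], 0.0, atol=1e-6)
        assert C[0, 0] == pytest.approx(0.3, abs=1e-6)

    def test_constant_basis_closed_form(self, rng):
        # single class, N = P = 1: the solution of the normal equations is
        # the responsibility-weighted mean residual
        vals = rng.normal(1.5, 0.4, 25)
        w = rng.uniform(0.1, 1.0, 25)
        data = flat_image(vals)
        resp = Responsibilities(w[:, None] / w[:, None])
        resp.weights = np.ones((25, 1))  # rows must sum to one
        C = update_bias(data, Responsibilities(np.ones((25, 1))), [[1.0]],
                        np.array([[[0.2]]]), constant_basis(data))
        assert C[0, 0] == pytest.approx(np.mean(vals - 1.0), abs=1e-10)
        # weighted version via a two-class split (weights w and 1-w): class
        # contributions couple through the shared bias coefficient
        resp2 = Responsibilities(np.stack([w, 1 - w], axis=1))
        C2 = update_bias(data, resp2, [[1.0], [1.0]],
                         np.array([[[0.2]], [[0.2]]]), constant_basis(data))
        assert C2[0, 0] == pytest.approx(np.mean(vals - 1.0), abs=1e-10)

    def test_solves_normal_equations_exactly(self, rng):
        grid = (12, 12)
        mask = np.ones(grid, bool)
        basis = make_bias_basis(grid, mask, (1, 1))
        vals = rng.normal(0, 1, (144, 2))
        data = ImageData(vals, mask, grid)
        W = rng.dirichlet([1, 1], 144)
        mu = np.array([[0.0, 0.0], [1.0, 0.5]])
        cov = np.array([[[1.0, 0.3], [0.3, 1.0]], [[0.5, -0.1], [-0.1, 0.8]]])
        C = update_bias(data, Responsibilities(W), mu, cov, basis)
        # residual of the stationarity condition
        lam = np.linalg.inv(cov)
        resid = vals - basis.values @ C.T
        G = np.zeros_like(C)
        for k in range(2):
            e = resid - mu[k]
            G += (lam[k] @ (W[:, k][:, None] * e).T) @ basis.values
        scale = np.abs(vals).sum()
        assert np.abs(G).max() / scale < 1e-8

    def test_smooth_bias_recovered_with_high_correlation(self, rng):
        grid = (24, 24)
        mask = np.ones(grid, bool)
        basis = make_bias_basis(grid, mask, (2, 2))
        c_true = np.zeros((1, basis.n_funcs))
        c_true[0, 1:] = rng.normal(0, 0.1, basis.n_funcs - 1)
        bias = (basis.values @ c_true.T)[:, 0]
        vals = 2.0 + bias + rng.normal(0, 0.05, 576)
        data = ImageData(vals[:, None], mask, grid)
        C = update_bias(data, Responsibilities(np.ones((576, 1))), [[2.0]],
                        np.array([[[0.0025]]]), basis)
        fit = (basis.values @ C.T)[:, 0]
        r = np.corrcoef(fit - fit.mean(), bias - bias.mean())[0, 1]
        assert r > 0.99


class TestEMObjective:
    def test_em_cycle_never_decreases_evidence(self, rng):
        grid = (16, 16)
        mask = np.ones(grid, bool)
        basis = make_bias_basis(grid, mask, (1, 1))
        labels = rng.integers(0, 2, 256)
        vals = np.where(labels == 0, rng.normal(0, 0.5, 256),
                        rng.normal(2, 0.7, 256))
        data = ImageData(vals[:, None], mask, grid)
        prior = np.full((256, 2), 0.5)
        model = IntensityModel(means=[[-0.5], [2.5]],
                               covariances=np.ones((2, 1, 1)),
                               bias_coeffs=np.zeros((1, basis.n_funcs)))
        prev = it.log_evidence(data, model, basis, prior)
        for _ in range(8):
            resp = compute_responsibilities(data, model, basis, prior)
            means, covs = update_gaussians(data, resp, basis,
                                           model.bias_coeffs)
            C = update_bias(data, resp, means, covs, basis)
            model = IntensityModel(means=means, covariances=covs,
                                   bias_coeffs=C)
            cur = it.log_evidence(data, model, basis, prior)
            assert cur >= prev - 1e-8 * abs(prev)
            prev = cur
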