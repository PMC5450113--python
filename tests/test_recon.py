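import numpy as np
import pytest
from scipy.optimize import minimize

import ddtv_pat as dp
from ddtv_pat.orientation import OrientationField, estimate_orientation_field
from ddtv_pat.recon import (
    ReconConfig,
    _grad,
    _grad_adjoint,
    ddtv_prox,
    ddtv_value,
    grad_step,
    reconstruct_ddtv,
    reconstruct_fbp,
    reconstruct_tv,
    tv_value,
)
from ddtv_pat.signal_sim import differentiate_to_pressure, simulate_spherical_means


def uniform_field(shape, theta=0.0, alpha=1.0, block=5):
    th = np.full(shape, float(theta))
    al = np.full(shape, float(alpha))
    C = np.zeros(shape)
    return OrientationField(th, C, al, block)


def smoothed_abs_objective(f, field, lam, eps=1e-12):
    """Exact discrete objective 0.5||A-f||^2 + lam * DDTV(A), smoothed."""

    def obj(x):
        A = x.reshape(f.shape)
        G = _grad(A)
        c, s = np.cos(field.theta), np.sin(field.theta)
        q1 = field.alpha * (c * G[0] + s * G[1])
        q2 = -s * G[0] + c * G[1]
        ddtv = np.sum(np.sqrt(q1**2 + q2**2 + eps))
        return 0.5 * np.sum((A - f) ** 2) + lam * ddtv

    return obj


class TestGradDivAdjointness:
    def test_exact_transpose(self, rng):
        A = rng.standard_normal((9, 7))
        P = rng.standard_normal((2, 9, 7))
        lhs = np.sum(_grad(A) * P)
        rhs = np.sum(A * _grad_adjoint(P))
        assert lhs == pytest.approx(rhs, rel=1e-13)


class TestDdtvValue:
    def test_reduces_to_tv_with_unit_alpha(self, rng):
        A = rng.random((12, 12))
        field = uniform_field(A.shape, theta=0.7, alpha=1.0)
        assert ddtv_value(A, field) == pytest.approx(tv_value(A), rel=1e-12)

    def test_constant_image_zero(self):
        field = uniform_field((8, 8))
        assert ddtv_value(np.ones((8, 8)), field) == 0.0

    @pytest.mark.parametrize("theta,expected", [(0.0, 2.0), (np.pi / 2, 1.0)])
    def test_single_gradient_ellipse_support(self, theta, expected):
        """sup over the ellipse of <g, p> for g = (1, 0), alpha = 2."""
        # build a 2x2 image whose only nonzero gradient entry is g1 = 1 at (1,*)
        A = np.array([[0.0, 0.0], [1.0, 1.0]])
        field = uniform_field(A.shape, theta=theta, alpha=2.0)
        # dense sampling of the ellipse boundary as the independent oracle
        phi = np.linspace(0, 2 * np.pi, 100000)
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        pts = R @ np.vstack([2.0 * np.cos(phi), np.sin(phi)])
        sup = np.max(pts[0])  # <(1,0), p> over ellipse boundary
        # two gradient entries contribute (g1 at (1,0) and (1,1))
        assert ddtv_value(A, field) == pytest.approx(2 * sup, rel=1e-6)
        assert sup == pytest.approx(expected, rel=1e-6)


class TestGradStep:
    def test_zero_residual_fixed_point(self, small_problem, rng):
        grid, geom, sampling, W = small_problem
        A = rng.random(grid.shape)
        g = dp.forward_project(W, A)
        out, res = grad_step(W, A, g, W.spectral_norm())
        np.testing.assert_allclose(out, A, atol=1e-12)
        assert res == pytest.approx(0.0, abs=1e-12)

    def test_zero_start_is_scaled_backprojection(self, small_problem, rng):
        grid, geom, sampling, W = small_problem
        g = dp.forward_project(W, rng.random(grid.shape))
        out, _ = grad_step(W, np.zeros(grid.shape), g, W.spectral_norm())
        np.testing.assert_allclose(
            out, W.adjoint_values(g.values) / W.spectral_norm() ** 2, rtol=1e-12)

    def test_fidelity_non_increasing(self, small_problem, rng):
        grid, geom, sampling, W = small_problem
        g = dp.forward_project(W, rng.random(grid.shape))
        sigma = W.spectral_norm()
        A = rng.standard_normal(grid.shape)
        for _ in range(5):
            before = np.sum((W.forward_values(A) - g.values) ** 2)
            A, _ = grad_step(W, A, g, sigma)
            after = np.sum((W.forward_values(A) - g.values) ** 2)
            assert after <= before * (1 + 1e-12)


class TestDdtvProx:
    def test_constant_input_unchanged(self):
        f = np.full((10, 10), 2.5)
        field = uniform_field(f.shape, alpha=2.0, theta=0.3)
        out, Gamma = ddtv_prox(f, field, 0.1, 50)
        np.testing.assert_allclose(out, f, atol=1e-12)
        assert not Gamma.any()

    def test_dual_feasibility_every_iteration(self, rng):
        f = rng.standard_normal((16, 16))
        field = uniform_field(f.shape, alpha=3.0, theta=1.0)
        Gamma = None
        for _ in range(20):
            _, Gamma = ddtv_prox(f, field, 0.05, 1, Gamma)
            norms = np.hypot(Gamma[0], Gamma[1])
            assert norms.max() <= 1.0 + 1e-12

    def test_matches_brute_force_tv_denoiser(self, rng):
        f = rng.random((8, 8))
        field = uniform_field(f.shape, alpha=1.0)
        lam = 0.1
        out, _ = ddtv_prox(f, field, lam, 3000)
        obj = smoothed_abs_objective(f, field, lam)
        res = minimize(obj, f.ravel(), method="L-BFGS-B",
                       options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12})
        ref = res.x.reshape(f.shape)
        # the general-purpose optimizer stalls slightly on the nonsmooth
        # objective: require close images and a prox objective at least as low
        assert np.linalg.norm(out - ref) / np.linalg.norm(ref) < 5e-3
        assert obj(out.ravel()) <= res.fun + 1e-3

    @pytest.mark.parametrize("theta,alpha", [(0.4, 2.0), (2.0, 3.0)])
    def test_matches_brute_force_objective_4x4(self, rng, theta, alpha):
        f = rng.random((4, 4))
        field = uniform_field(f.shape, theta=theta, alpha=alpha)
        lam = 0.15
        out, _ = ddtv_prox(f, field, lam, 5000)
        obj = smoothed_abs_objective(f, field, lam)
        res = minimize(obj, f.ravel(), method="L-BFGS-B",
                       options={"maxiter": 50000, "ftol": 1e-16, "gtol": 1e-13})
        assert obj(out.ravel()) <= res.fun + 1e-3


class TestReconstruct:
    def test_zero_data_zero_image(self, small_problem):
        grid, geom, sampling, W = small_problem
        g = dp.Sinogram(np.zeros((geom.n_views, sampling.n_samples)),
                        "integrated_g", geom, sampling)
        cfg = ReconConfig(outer_iters=3, data_iters=5, inner_iters=3)
        for fn in (reconstruct_ddtv, reconstruct_tv):
            res = fn(g, W, cfg)
            assert not res.image.any()

    def test_tv_is_ddtv_with_unit_alpha(self, small_problem, rng):
        grid, geom, sampling, W = small_problem
        g = dp.forward_project(W, rng.random(grid.shape))
        lam = 0.01
        cfg_tv = ReconConfig(lambda_reg=lam, tv_lambda_schedule=(lam, lam),
                             outer_iters=4, data_iters=10, inner_iters=5,
                             noise_scale=0.0)
        cfg_dd = ReconConfig(lambda_reg=lam, alpha_max=1.0, noise_scale=0.0,
                             outer_iters=4, data_iters=10, inner_iters=5)
        a = reconstruct_tv(g, W, cfg_tv).image
        b = reconstruct_ddtv(g, W, cfg_dd).image
        np.testing.assert_array_equal(a, b)  # bit-identical iterates

    def test_pressure_domain_rejected(self, small_problem):
        grid, geom, sampling, W = small_problem
        p = dp.Sinogram(np.zeros((geom.n_views, sampling.n_samples)),
                        "pressure_p", geom, sampling)
        with pytest.raises(ValueError):
            reconstruct_ddtv(p, W, ReconConfig(outer_iters=1, data_iters=1))

    def test_noise_free_recovery_small(self, small_problem):
        """A smooth blob is recovered accurately from 8-view clean data."""
        grid, geom, sampling, _ = small_problem
        A = dp.disk(16, radius_px=4.0)
        Wq = dp.build_quadrature_matrix(geom, grid, sampling, upsample=2)
        g = simulate_spherical_means(A, grid, geom, sampling, upsample=8)
        cfg = ReconConfig(lambda_reg=5e-5, outer_iters=5, data_iters=60)
        res = reconstruct_ddtv(g, Wq, cfg)
        assert dp.distance_d(res.image, A) < 0.12


class TestFbp:
    def test_zero_data(self, small_problem):
        grid, geom, sampling, _ = small_problem
        p = dp.Sinogram(np.zeros((geom.n_views, sampling.n_samples)),
                        "pressure_p", geom, sampling)
        res = reconstruct_fbp(p, grid)
        assert not res.image.any()

    def test_linear_geometry_rejected(self, small_problem):
        grid, *_ = small_problem
        geom = dp.linear_scan(8, 40.0)
        sampling = dp.AcousticSampling(1500.0, 1e-7, 64)
        p = dp.Sinogram(np.zeros((8, 64)), "pressure_p", geom, sampling)
        with pytest.raises(ValueError):
            reconstruct_fbp(p, grid)

    def test_point_absorber_localization(self):
        n = 64
        grid = dp.make_grid(n, n, 64.0)
        geom = dp.circular_scan(180, 40.0)
        sampling = dp.default_sampling(grid, geom)
        A = dp.point_absorber(n, center_px=(6.0, -9.0))
        g = simulate_spherical_means(A, grid, geom, sampling, upsample=4)
        p = differentiate_to_pressure(g)
        res = reconstruct_fbp(p, grid)
        peak = np.unravel_index(np.argmax(res.image), res.image.shape)
        true = np.unravel_index(np.argmax(A), A.shape)
        assert abs(peak[0] - true[0]) <= 1 and abs(peak[1] - true[1]) <= 1

    def test_disk_boundary_recovery(self):
        n = 64
        grid = dp.make_grid(n, n, 64.0)
        geom = dp.circular_scan(180, 40.0)
        sampling = dp.default_sampling(grid, geom)
        A = dp.disk(n, radius_px=10.0)
        g = simulate_spherical_means(A, grid, geom, sampling, upsample=4)
        res = reconstruct_fbp(differentiate_to_pressure(g), grid)
        profile = res.image[:, n // 2 - 1]  # radial cut through the center
        half = np.nonzero(profile >= 0.5 * profile.max())[0]
        # half-maximum edges within 2 px of the true disk boundary
        center = (n - 1) / 2
        assert abs((center - half[0]) - 10.0) <= 2.0
        assert abs((half[-1] - center) - 10.0) <= 2.0
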