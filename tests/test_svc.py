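import math

import numpy as np
import pytest
from scipy import integrate

from steinselect import (
    BackgroundPolicy,
    KernelSpec,
    background_dim,
    calibrate_temperature,
    defective_scores,
    fit_min_nksd,
    gaussian_model,
    gen_toy,
    svc_bic,
    svc_exact_quadratic,
    svc_laplace,
    svc_score,
    svc_variational,
)
from steinselect.svc import NKSDObjective, gaussian_conjugate_logml

PY_POLICY = BackgroundPolicy(mode="pitman_yor", alpha=0.5, nu=1.0, D=0.2)
CONST5 = BackgroundPolicy(mode="constant", m_const=5.0)


class TestBackgroundDim:
    def test_pitman_yor_multiplier_at_2000(self):
        assert background_dim(PY_POLICY, 1, 2000) == pytest.approx(20.19, abs=0.01)

    def test_pitman_yor_exceeds_two_first_at_20(self):
        first = next(N for N in range(1, 100) if background_dim(PY_POLICY, 1, N) > 2)
        assert first == 20

    def test_empty_background_is_zero_for_every_mode(self):
        for pol in (PY_POLICY, CONST5, BackgroundPolicy(mode="per_dim_sqrtN", c_b=2.0)):
            assert background_dim(pol, 0, 500) == 0.0

    def test_sqrtN_mode(self):
        pol = BackgroundPolicy(mode="per_dim_sqrtN", c_b=1.5)
        assert background_dim(pol, 2, 400) == pytest.approx(1.5 * 2 * 20.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            BackgroundPolicy(mode="pitman_yor", alpha=1.5)
        with pytest.raises(ValueError):
            BackgroundPolicy(mode="nope")
        with pytest.raises(ValueError):
            background_dim(PY_POLICY, -1, 10)


class TestFitMinNKSD:
    def test_two_point_quadratic_vertex(self, unit_rbf):
        m = gaussian_model(True, np.eye(1))
        fit = fit_min_nksd(m, np.array([[0.0], [1.0]]), unit_rbf)
        assert fit.theta[0] == pytest.approx(0.5, abs=1e-10)
        assert fit.nksd_min == pytest.approx(-1.25, abs=1e-10)

    def test_expfam_vertex_matches_minus_half_AinvB(self, unit_rbf, rng):
        m = gaussian_model(True, np.eye(2))
        X = rng.normal(size=(200, 2))
        obj = NKSDObjective(m, X, unit_rbf)
        A, B, _ = obj.quadratic
        fit = fit_min_nksd(m, X, unit_rbf, objective=obj)
        assert np.allclose(fit.theta, np.linalg.solve(A, -B / 2.0), atol=1e-6)

    def test_numeric_path_agrees_with_quadratic(self, unit_rbf, rng):
        # strip the quadratic shortcut and check the optimizer lands on the vertex
        m = gaussian_model(True, np.eye(2))
        X = rng.normal(size=(150, 2))
        ref = fit_min_nksd(m, X, unit_rbf)
        m_slow = gaussian_model(True, np.eye(2))
        m_slow.affine_linear = None
        fit = fit_min_nksd(m_slow, X, unit_rbf)
        assert np.allclose(fit.theta, ref.theta, atol=1e-4)
        assert fit.grad_norm < 1e-3

    def test_parameter_recovery_well_specified(self, unit_rbf):
        ests = []
        for rep in range(10):
            X = gen_toy(1500, np.eye(2), seed=500 + rep) + np.array([0.7, -0.2])
            m = gaussian_model(True, np.eye(2))
            ests.append(fit_min_nksd(m, X, unit_rbf, with_hessian=False).theta)
        ests = np.array(ests)
        se = ests.std(axis=0, ddof=1) / math.sqrt(len(ests))
        assert np.all(np.abs(ests.mean(axis=0) - [0.7, -0.2]) < 3 * se + 1e-9)


class TestExactBackend:
    def test_constant_integrand(self):
        res = svc_exact_quadratic(np.zeros((1, 1)), np.zeros(1), -1.0,
                                  np.zeros(1), 10 * np.eye(1), 5.0, 100, 3.0)
        assert res.log_svc == pytest.approx(-(100 / 5.0) * (-1.0)
                                            + 1.5 * math.log(2 * math.pi / 100))

    def test_matches_1d_quadrature(self):
        res = svc_exact_quadratic(np.array([[1.0]]), np.array([-1.0]), -1.0,
                                  np.zeros(1), 10 * np.eye(1), 5.0, 100, 0.0)
        f = lambda th: math.exp(-(100 / 5) * (th * th - th - 1)) * math.exp(
            -th * th / 20) / math.sqrt(2 * math.pi * 10)
        val, _ = integrate.quad(f, -10, 10)
        assert res.log_svc == pytest.approx(math.log(val), rel=1e-8)

    def test_matches_2d_tensor_quadrature(self, unit_rbf):
        X = gen_toy(300, np.eye(2), seed=11)
        m = gaussian_model(True, np.eye(2))
        obj = NKSDObjective(m, X, unit_rbf)
        A, B, C = obj.quadratic
        res = svc_score(m, X, unit_rbf, 5.0, CONST5, 0, backend="exact")
        g = lambda a, b: math.exp(
            -(300 / 5) * (np.array([a, b]) @ A @ np.array([a, b]) + B @ [a, b] + C)
        ) * math.exp(-(a * a + b * b) / 20) / (2 * math.pi * 10)
        val, _ = integrate.dblquad(g, -2, 2, -2, 2)
        assert res.log_svc - res.background_volume_term == pytest.approx(
            math.log(val), abs=1e-6
        )


class TestLaplaceAndBIC:
    def test_laplace_close_to_exact_at_n1000(self, unit_rbf):
        X = gen_toy(1000, np.eye(2), seed=3)
        m = gaussian_model(True, np.eye(2))
        ex = svc_score(m, X, unit_rbf, 5.0, CONST5, 0, backend="exact")
        la = svc_laplace(m, X, unit_rbf, 5.0, CONST5, 0)
        assert abs(la.log_svc - ex.log_svc) / abs(ex.log_svc) < 0.01

    def test_fixed_parameter_model_reduces_to_fit_plus_background(self, unit_rbf):
        X = gen_toy(200, np.eye(2), seed=4)
        m = gaussian_model(False, np.eye(2))
        la = svc_laplace(m, X, unit_rbf, 5.0, CONST5, 1)
        obj = NKSDObjective(m, X, unit_rbf)
        expect = -(200 / 5.0) * obj(np.zeros(0)) + 0.5 * 5.0 * math.log(2 * math.pi / 200)
        assert la.log_svc == pytest.approx(expect, abs=1e-10)

    def test_temperature_doubling_identity(self, unit_rbf):
        # T -> 2T halves the fit term and adds (m_F/2) log 2 via the determinant
        X = gen_toy(400, np.eye(2), seed=5)
        m = gaussian_model(True, np.eye(2))
        r1 = svc_laplace(m, X, unit_rbf, 5.0, CONST5, 0)
        r2 = svc_laplace(m, X, unit_rbf, 10.0, CONST5, 0)
        assert r2.fit_term == pytest.approx(r1.fit_term / 2.0, rel=1e-10)
        assert r2.foreground_volume_term - r1.foreground_volume_term == pytest.approx(
            (m.param_dim / 2.0) * math.log(2.0), abs=1e-10
        )

    def test_bic_identities(self, unit_rbf):
        X = gen_toy(300, np.eye(2), seed=6)
        m = gaussian_model(True, np.eye(2))
        la = svc_laplace(m, X, unit_rbf, 5.0, CONST5, 1)
        bi = svc_bic(m, X, unit_rbf, 5.0, CONST5, 1)
        fit = fit_min_nksd(m, X, unit_rbf)
        H = fit.hessian / 5.0
        expect_gap = m.prior_logpdf(fit.theta) - 0.5 * np.linalg.slogdet(H)[1]
        assert la.log_svc - bi.log_svc == pytest.approx(expect_gap, abs=1e-8)
        # no volume terms at all
        m0 = gaussian_model(False, np.eye(2))
        b0 = svc_bic(m0, X, unit_rbf, 5.0, CONST5, 0)
        assert b0.log_svc == pytest.approx(b0.fit_term)

    def test_bic_exact_leading_order_agreement(self, unit_rbf):
        X = gen_toy(10000, np.eye(2), seed=7)
        m = gaussian_model(True, np.eye(2))
        ex = svc_score(m, X, unit_rbf, 5.0, CONST5, 0, backend="exact")
        bi = svc_bic(m, X, unit_rbf, 5.0, CONST5, 0)
        assert abs(bi.log_svc - ex.log_svc) / 10000 < 1e-3


class TestVariational:
    def test_bound_below_exact_and_tight_for_gaussian(self, unit_rbf):
        X = gen_toy(500, np.eye(2), seed=8)
        m = gaussian_model(True, np.eye(2))
        ex = svc_score(m, X, unit_rbf, 5.0, CONST5, 0, backend="exact")
        vr = svc_variational(m, X, unit_rbf, 5.0, CONST5, 0, steps=300, seed=0)
        assert vr.log_svc <= ex.log_svc + 1e-6
        assert ex.log_svc - vr.log_svc < 0.1

    def test_prior_family_zero_steps_is_prior_expectation(self, unit_rbf):
        # r fixed to the prior: entropy and prior terms cancel, leaving the
        # sampled prior expectation of the fit term
        X = gen_toy(300, np.eye(2), seed=9)
        m = gaussian_model(True, np.eye(2))
        vr = svc_variational(m, X, unit_rbf, 5.0, CONST5, 0, steps=0,
                             init="prior", seed=1)
        obj = NKSDObjective(m, X, unit_rbf)
        A, B, C = obj.quadratic
        mu0, S0 = m.gaussian_prior
        expect = -(300 / 5.0) * (float(mu0 @ A @ mu0) + float(np.diag(A) @ np.diag(S0))
                                 + float(B @ mu0) + C)
        assert vr.fit_term == pytest.approx(expect, rel=1e-9)

    def test_bound_trajectory_ascends(self, unit_rbf):
        X = gen_toy(300, np.eye(2), seed=10)
        m = gaussian_model(True, np.eye(2))
        m.affine_linear = None  # force the sampled-gradient path
        _, trace = svc_variational(m, X, unit_rbf, 5.0, CONST5, 0, steps=120,
                                   seed=0, init=np.zeros(2), n_samples=8,
                                   return_trace=True)
        smooth = np.convolve(trace, np.ones(30) / 30, mode="valid")
        assert smooth[-1] > smooth[0]

    def test_seeded_reproducibility(self, unit_rbf):
        X = gen_toy(200, np.eye(2), seed=12)
        m = gaussian_model(True, np.eye(2))
        a = svc_variational(m, X, unit_rbf, 5.0, CONST5, 0, steps=50, seed=3).log_svc
        b = svc_variational(m, X, unit_rbf, 5.0, CONST5, 0, steps=50, seed=3).log_svc
        assert a == b


class TestDefectiveScores:
    def test_kb_is_svc_without_background_volume(self, unit_rbf):
        X = gen_toy(300, np.eye(2), seed=13)
        m = gaussian_model(True, np.eye(2))
        svc = svc_score(m, X, unit_rbf, 5.0, CONST5, 1, backend="exact")
        kb = defective_scores(m, X, unit_rbf, 5.0, CONST5, 1, "kb", backend="exact")
        assert kb.log_svc == pytest.approx(svc.log_svc - svc.background_volume_term)

    def test_kd_is_bic_without_foreground_volume(self, unit_rbf):
        X = gen_toy(300, np.eye(2), seed=14)
        m = gaussian_model(True, np.eye(2))
        bi = svc_bic(m, X, unit_rbf, 5.0, CONST5, 1)
        kd = defective_scores(m, X, unit_rbf, 5.0, CONST5, 1, "kd")
        assert kd.log_svc == pytest.approx(
            bi.log_svc - 0.5 * m.param_dim * math.log(2 * math.pi / 300), abs=1e-9
        )

    def test_ka_matches_quadrature_marginal_likelihood(self):
        X = np.array([[0.3], [-0.8]])
        val = gaussian_conjugate_logml(X, np.eye(1), np.zeros(1), 10 * np.eye(1))
        f = lambda th: math.exp(
            -0.5 * ((X[0, 0] - th) ** 2 + (X[1, 0] - th) ** 2)
        ) / (2 * math.pi) * math.exp(-th * th / 20) / math.sqrt(2 * math.pi * 10)
        ref, _ = integrate.quad(f, -20, 20)
        assert val == pytest.approx(math.log(ref), rel=1e-8)

    def test_ka_requires_conjugate_model(self, unit_rbf):
        from steinselect import ppca_model

        with pytest.raises(ValueError, match="conjugate"):
            defective_scores(ppca_model(4, 2), np.zeros((10, 4)), unit_rbf,
                             1.0, CONST5, 0, "ka")


class TestCalibrateTemperature:
    @staticmethod
    def _simulator(rng):
        theta = rng.normal(size=1)
        return theta + rng.standard_normal((200, 1)), theta

    def test_degenerate_grid_returns_it(self, unit_rbf):
        best, cov = calibrate_temperature(
            lambda: gaussian_model(True, np.eye(1)), self._simulator, [2.0],
            replicates=5, seed=0, spec=unit_rbf,
        )
        assert best == 2.0

    def test_coverage_monotone_in_temperature(self, unit_rbf):
        # interval width scales as sqrt(T), so coverage rises with T
        best, cov = calibrate_temperature(
            lambda: gaussian_model(True, np.eye(1)), self._simulator,
            [0.2, 1.0, 5.0, 25.0], replicates=40, seed=1, spec=unit_rbf,
        )
        vals = [cov[t] for t in sorted(cov)]
        assert all(b >= a - 0.05 for a, b in zip(vals, vals[1:]))

    def test_reproducible_under_seed(self, unit_rbf):
        args = (lambda: gaussian_model(True, np.eye(1)), self._simulator, [0.5, 2.0])
        a = calibrate_temperature(*args, replicates=10, seed=7, spec=unit_rbf)
        b = calibrate_temperature(*args, replicates=10, seed=7, spec=unit_rbf)
        assert a == b

    def test_empty_grid_rejected(self, unit_rbf):
        with pytest.raises(ValueError):
            calibrate_temperature(lambda: gaussian_model(True, np.eye(1)),
                                  self._simulator, [], spec=unit_rbf)
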