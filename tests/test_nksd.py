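import math

import numpy as np
import pytest

from steinselect import (
    KernelSpec,
    LinearScoreMoments,
    expfam_quadratic,
    nksd_population_mc,
    nksd_ustat,
    stein_u_term,
)

E_HALF = math.exp(-0.5)


def std_normal_score(Z):
    return -np.atleast_2d(Z)


class TestSteinUTerm:
    def test_origin_only_trace_survives(self, unit_rbf):
        assert stein_u_term([0.0], [0.0], std_normal_score, unit_rbf) == pytest.approx(1.0)

    def test_unit_separation_value(self, unit_rbf):
        val = stein_u_term([0.0], [1.0], std_normal_score, unit_rbf)
        assert val == pytest.approx(-E_HALF, abs=1e-12)

    def test_symmetric_in_arguments(self, unit_rbf, rng):
        for _ in range(20):
            x, y = rng.normal(size=2), rng.normal(size=2)
            a = stein_u_term(x, y, std_normal_score, unit_rbf)
            b = stein_u_term(y, x, std_normal_score, unit_rbf)
            assert a == pytest.approx(b, abs=1e-12)

    def test_non_finite_score_rejected(self, unit_rbf):
        with pytest.raises(ValueError, match="non-finite"):
            stein_u_term([0.0], [1.0], lambda Z: Z * np.inf, unit_rbf)


class TestNKSDUstat:
    def test_two_point_worked_example(self, unit_rbf):
        est = nksd_ustat(np.array([[0.0], [1.0]]), std_normal_score, unit_rbf)
        assert est.value == pytest.approx(-1.0, abs=1e-14)
        assert est.value == est.numerator / est.denominator
        assert est.denominator > 0

    def test_single_observation_zero_by_convention(self, unit_rbf):
        with pytest.warns(UserWarning, match="convention"):
            est = nksd_ustat(np.array([[3.0]]), std_normal_score, unit_rbf)
        assert est.value == 0.0

    def test_empty_data_rejected(self, unit_rbf):
        with pytest.raises(ValueError, match="empty"):
            nksd_ustat(np.empty((0, 1)), std_normal_score, unit_rbf)

    def test_result_independent_of_chunk_size(self, unit_rbf, rng):
        X = rng.normal(size=(301, 2))
        vals = {nksd_ustat(X, std_normal_score, unit_rbf, chunk=c).value for c in (7, 64, 1000)}
        assert max(vals) - min(vals) < 1e-12

    def test_row_permutation_invariance(self, unit_rbf, rng):
        X = rng.normal(size=(120, 2))
        v1 = nksd_ustat(X, std_normal_score, unit_rbf).value
        v2 = nksd_ustat(X[rng.permutation(120)], std_normal_score, unit_rbf).value
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_well_specified_concentration(self, unit_rbf):
        # O(1/N) concentration under the true model: the typical estimate at
        # N = 5000 sits within 5/N of zero (median over replicate draws)
        vals = []
        for seed in range(8):
            X = np.random.default_rng(seed).standard_normal((5000, 1))
            vals.append(abs(nksd_ustat(X, std_normal_score, unit_rbf).value))
        assert np.median(vals) < 5.0 / 5000

    def test_float32_agrees_with_float64(self, unit_rbf, rng):
        X = rng.normal(size=(400, 2))
        v64 = nksd_ustat(X, std_normal_score, unit_rbf).value
        v32 = nksd_ustat(X, std_normal_score, unit_rbf, dtype=np.float32).value
        assert v32 == pytest.approx(v64, abs=1e-5)


class TestPopulationOracle:
    def test_zero_iff_same_distribution(self, unit_rbf):
        val, se = nksd_population_mc(
            lambda r, n: r.standard_normal((n, 1)),
            std_normal_score, std_normal_score, unit_rbf, 5000, 3,
        )
        assert abs(val) <= 3 * max(se, 1e-12)

    def test_strictly_positive_when_different(self, unit_rbf):
        val, se = nksd_population_mc(
            lambda r, n: r.standard_normal((n, 1)),
            std_normal_score, lambda Z: -Z / 2.0, unit_rbf, 20000, 3,
        )
        assert val > 3 * se

    def test_agrees_with_ustat_estimator(self, unit_rbf):
        # two independent estimators of the same population quantity
        val, se = nksd_population_mc(
            lambda r, n: r.standard_normal((n, 1)),
            std_normal_score, lambda Z: -Z / 2.0, unit_rbf, 20000, 3,
        )
        X = np.random.default_rng(99).standard_normal((20000, 1))
        est = nksd_ustat(X, lambda Z: -Z / 2.0, unit_rbf, dtype=np.float32).value
        # the u-statistic has comparable sampling error to the oracle
        assert est == pytest.approx(val, abs=3 * se * 2)

    def test_subsystem_additivity(self, unit_rbf):
        # block-independent p and q with a factorizing kernel: the 2-D NKSD
        # equals the sum of the per-block values (well-specified block adds 0)
        v2, se2 = nksd_population_mc(
            lambda r, n: r.standard_normal((n, 2)),
            lambda Z: -Z,
            lambda Z: np.column_stack([-Z[:, 0], -Z[:, 1] / 2.0]),
            unit_rbf, 20000, 0, dtype=np.float32,
        )
        v1, se1 = nksd_population_mc(
            lambda r, n: r.standard_normal((n, 1)),
            std_normal_score, lambda Z: -Z / 2.0, unit_rbf, 20000, 0, dtype=np.float32,
        )
        assert v2 == pytest.approx(v1, abs=3 * math.hypot(se1, se2))

    def test_tiny_mc_rejected(self, unit_rbf):
        with pytest.raises(ValueError):
            nksd_population_mc(lambda r, n: r.standard_normal((n, 1)),
                               std_normal_score, std_normal_score, unit_rbf, 1, 0)


class TestExpfamQuadratic:
    def test_two_point_gaussian_location(self, unit_rbf):
        X = np.array([[0.0], [1.0]])
        A, B, C = expfam_quadratic(
            X,
            lambda Z: np.broadcast_to(np.eye(1), (len(Z), 1, 1)),
            lambda Z: -Z,
            unit_rbf,
        )
        assert A[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert B[0] == pytest.approx(-1.0, abs=1e-12)
        assert C == pytest.approx(-1.0, abs=1e-12)
        # minimized at the sample mean
        assert -B[0] / (2 * A[0, 0]) == pytest.approx(0.5)

    @pytest.mark.parametrize("spec_name", ["rbf", "imq", "blocks"])
    def test_quadratic_matches_ustat_at_random_theta(self, spec_name, rng):
        spec = {
            "rbf": KernelSpec(bandwidth=1.4),
            "imq": KernelSpec(family="imq", bandwidth=1.0),
            "blocks": KernelSpec(bandwidth=1.0, blocks=((0, 2), (1,))),
        }[spec_name]
        X = rng.normal(size=(60, 3))
        Sigma_inv = np.linalg.inv(np.array([[2.0, 0.3, 0], [0.3, 1.0, 0], [0, 0, 0.7]]))
        A, B, C = expfam_quadratic(
            X,
            lambda Z: np.broadcast_to(Sigma_inv, (len(Z), 3, 3)).copy(),
            lambda Z: -np.atleast_2d(Z) @ Sigma_inv,
            spec,
        )
        for _ in range(20):
            th = rng.normal(size=3)
            direct = nksd_ustat(X, lambda Z: (th - np.atleast_2d(Z)) @ Sigma_inv, spec).value
            assert th @ A @ th + B @ th + C == pytest.approx(direct, abs=1e-10)

    def test_curvature_asymptotically_convex(self, unit_rbf):
        X = np.random.default_rng(0).standard_normal((2000, 2))
        mom = LinearScoreMoments(X, unit_rbf, dtype=np.float32)
        A, _, _ = mom.location_quadratic(np.eye(2))
        assert np.linalg.eigvalsh(A).min() > -1e-8


class TestLinearScoreMoments:
    def test_affine_evaluation_matches_ustat(self, rng):
        for spec in (KernelSpec(bandwidth=1.0), KernelSpec(family="imq", bandwidth=1.2),
                     KernelSpec(bandwidth=0.9, blocks=((1,), (0, 2)))):
            X = rng.normal(size=(80, 3))
            mom = LinearScoreMoments(X, spec)
            W = rng.normal(size=(3, 3))
            m = rng.normal(size=3)
            direct = nksd_ustat(X, lambda Z: np.atleast_2d(Z) @ W.T + m, spec).value
            assert mom.nksd_affine(W, m) == pytest.approx(direct, abs=1e-10)

    def test_location_quadratic_consistent_with_affine(self, rng):
        X = rng.normal(size=(50, 2))
        mom = LinearScoreMoments(X, KernelSpec(bandwidth=1.0))
        Si = np.linalg.inv(np.array([[1.5, 0.2], [0.2, 0.8]]))
        A, B, C = mom.location_quadratic(Si)
        th = rng.normal(size=2)
        assert th @ A @ th + B @ th + C == pytest.approx(
            mom.nksd_affine(-Si, Si @ th), abs=1e-10
        )
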