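import numpy as np
import pytest

from steinselect import (
    BackgroundPolicy,
    ForegroundCandidate,
    KernelSpec,
    compare,
    gaussian_model,
    gen_toy,
    loo_scan,
    project,
    subset_search,
    svc_score,
    transfer_optimum,
)
from steinselect.builders import gaussian_loo_builder, gaussian_subset_builder

CONST5 = BackgroundPolicy(mode="constant", m_const=5.0)


class TestProject:
    def test_identity_projection(self, rng):
        X = rng.normal(size=(10, 3))
        cand = ForegroundCandidate("full", V=np.eye(3))
        assert np.allclose(project(X, cand), X)

    def test_column_subset(self, rng):
        X = rng.normal(size=(10, 3))
        cand = ForegroundCandidate("c0", columns=(0,))
        assert np.allclose(project(X, cand), X[:, :1])

    def test_projection_contracts_frobenius_norm(self, rng):
        X = rng.normal(size=(20, 4))
        V, _ = np.linalg.qr(rng.normal(size=(4, 2)))
        cand = ForegroundCandidate("v", V=V)
        assert np.linalg.norm(project(X, cand)) <= np.linalg.norm(X) + 1e-12

    def test_non_orthonormal_rejected(self, rng):
        cand = ForegroundCandidate("bad", V=np.ones((3, 2)))
        with pytest.raises(ValueError, match="orthonormal"):
            project(rng.normal(size=(5, 3)), cand)

    def test_requires_exactly_one_spec(self):
        with pytest.raises(ValueError):
            ForegroundCandidate("x")


class TestCompare:
    def _two_results(self, unit_rbf):
        X = gen_toy(200, np.eye(2), seed=1)
        m1 = gaussian_model(True, np.eye(2))
        m2 = gaussian_model(True, 2 * np.eye(2))
        r1 = svc_score(m1, X, unit_rbf, 5.0, CONST5, 0, backend="exact")
        r2 = svc_score(m2, X, unit_rbf, 5.0, CONST5, 0, backend="exact")
        return r1, r2

    def test_identical_results_compare_to_zero(self, unit_rbf):
        r1, _ = self._two_results(unit_rbf)
        assert compare(r1, r1) == 0.0

    def test_antisymmetry(self, unit_rbf):
        r1, r2 = self._two_results(unit_rbf)
        assert compare(r1, r2) == pytest.approx(-compare(r2, r1))

    def test_mismatched_configs_rejected(self, unit_rbf):
        X = gen_toy(200, np.eye(2), seed=1)
        m = gaussian_model(True, np.eye(2))
        r1 = svc_score(m, X, unit_rbf, 5.0, CONST5, 0, backend="exact")
        r2 = svc_score(m, X, unit_rbf, 1.0, CONST5, 0, backend="exact")
        with pytest.raises(ValueError, match="configuration"):
            compare(r1, r2)


class TestTransferOptimum:
    def test_identity_transfer_at_shared_optimum(self, rng):
        H = np.eye(3) * 2.0
        theta0 = rng.normal(size=3)
        assert np.allclose(transfer_optimum(theta0, np.zeros(3), H), theta0)

    def test_exact_for_shared_curvature_quadratics(self, rng):
        # when both objectives share the Hessian, one Newton step solves the
        # second quadratic exactly
        A = np.array([[2.0, 0.3], [0.3, 1.0]])
        b1, b2 = rng.normal(size=2), rng.normal(size=2)
        theta0 = np.linalg.solve(2 * A, -b1)
        grad2 = 2 * A @ theta0 + b2
        expect = np.linalg.solve(2 * A, -b2)
        assert np.allclose(transfer_optimum(theta0, grad2, 2 * A), expect, atol=1e-10)

    def test_singular_hessian_beyond_jitter_raises(self):
        with pytest.raises(np.linalg.LinAlgError, match="re-optimize"):
            transfer_optimum(np.zeros(2), np.ones(2), -np.eye(2) * 1e3)


class TestLOOScan:
    def test_report_bookkeeping(self, unit_rbf):
        X = gen_toy(500, np.eye(2), seed=2)
        report = loo_scan(X, gaussian_loo_builder(2), spec=unit_rbf, T=5.0,
                          policy=CONST5, backend="bic")
        assert len(report.rows) == 3  # reference + d
        assert report.rows[0]["log_ratio"] == 0.0
        df = report.to_dataframe()
        assert set(df["decision"]) <= {"reference", "include", "exclude"}

    def test_misspecified_dimension_flagged_for_exclusion(self, unit_rbf):
        # variance-1/2 second dimension under a unit-covariance location model
        X = gen_toy(5000, np.diag([1.0, 0.5]), seed=3)
        report = loo_scan(X, gaussian_loo_builder(2), spec=unit_rbf, T=5.0,
                          policy=CONST5, backend="bic")
        ratios = {r["drops"]: r["log_ratio"] for r in report.rows[1:]}
        assert ratios["dim2"] > 0  # dropping the bad dimension helps
        assert ratios["dim2"] > ratios["dim1"]

    def test_transfer_matches_reoptimization(self, unit_rbf, rng):
        variances = np.array([1.0, 0.7, 1.4, 0.5])
        X = rng.standard_normal((2000, 4)) * np.sqrt(variances)
        common = dict(spec=unit_rbf, T=5.0, policy=CONST5, backend="bic")
        rt = loo_scan(X, gaussian_loo_builder(4), transfer=True, **common)
        rx = loo_scan(X, gaussian_loo_builder(4), transfer=False, **common)
        lt = np.array([r["log_ratio"] for r in rt.rows[1:]])
        lx = np.array([r["log_ratio"] for r in rx.rows[1:]])
        assert np.corrcoef(lt, lx)[0, 1] > 0.99
        for j in range(4):
            assert lt[j] == pytest.approx(lx[j], rel=0.05, abs=1.0)

    def test_column_relabeling_permutes_report(self, unit_rbf):
        X = gen_toy(1000, np.diag([1.0, 0.5]), seed=4)
        r1 = loo_scan(X, gaussian_loo_builder(2), spec=unit_rbf, T=5.0,
                      policy=CONST5, backend="bic", names=["a", "b"])
        r2 = loo_scan(X[:, ::-1].copy(), gaussian_loo_builder(2), spec=unit_rbf,
                      T=5.0, policy=CONST5, backend="bic", names=["b", "a"])
        d1 = {r["drops"]: r["log_ratio"] for r in r1.rows[1:]}
        d2 = {r["drops"]: r["log_ratio"] for r in r2.rows[1:]}
        for k in d1:
            assert d1[k] == pytest.approx(d2[k], rel=1e-6, abs=1e-6)

    def test_match_foreground_mb_mode(self, unit_rbf):
        X = gen_toy(400, np.eye(2), seed=5)
        report = loo_scan(X, gaussian_loo_builder(2), spec=unit_rbf, T=5.0,
                          policy=CONST5, backend="bic", mb_mode="match_foreground")
        for row in report.rows[1:]:
            assert row["m_B"] == pytest.approx(1.0)  # m_F0 - m_Fj = 2 - 1

    def test_seeded_bit_reproducibility(self, unit_rbf):
        X = gen_toy(300, np.eye(2), seed=6)
        kw = dict(spec=unit_rbf, T=5.0, policy=CONST5, backend="bic", seed=9)
        a = loo_scan(X, gaussian_loo_builder(2), **kw)
        b = loo_scan(X, gaussian_loo_builder(2), **kw)
        assert [r["log_ratio"] for r in a.rows] == [r["log_ratio"] for r in b.rows]


class TestSubsetSearch:
    def test_zero_steps_leaves_probabilities_at_half(self, unit_rbf, rng):
        X = rng.standard_normal((200, 3))
        probs, best, trace = subset_search(
            X, gaussian_subset_builder(3), spec=unit_rbf, T=5.0, policy=CONST5,
            backend="exact", steps=0, seed=0,
        )
        assert np.allclose(probs, 0.5)
        assert trace == []

    def test_identifies_misspecified_pair(self, unit_rbf):
        # dims 3 and 4 have variance 1/2 under a unit-covariance model
        rng = np.random.default_rng(21)
        X = rng.standard_normal((2000, 4)) * np.sqrt([1.0, 1.0, 0.5, 0.5])
        probs, best, _ = subset_search(
            X, gaussian_subset_builder(4), spec=unit_rbf, T=5.0, policy=CONST5,
            backend="exact", steps=150, lr=0.4, seed=0,
        )
        assert probs[0] > 0.9 and probs[1] > 0.9
        assert probs[2] < 0.1 and probs[3] < 0.1
        assert best == (0, 1)

    def test_wellspecified_full_set_preferred(self, unit_rbf):
        rng = np.random.default_rng(22)
        X = rng.standard_normal((2000, 4))
        probs, best, _ = subset_search(
            X, gaussian_subset_builder(4), spec=unit_rbf, T=5.0, policy=CONST5,
            backend="exact", steps=150, lr=0.4, seed=0,
        )
        assert np.all(probs > 0.5)

    def test_batch_of_one_rejected(self, unit_rbf, rng):
        with pytest.raises(ValueError, match="control variate"):
            subset_search(rng.standard_normal((50, 2)), gaussian_subset_builder(2),
                          spec=unit_rbf, batch=1)
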