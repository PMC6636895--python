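"""Likelihood, gradient and parameterization of the conditional model."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from lscggm.core import (
    CRFParameters,
    Dataset,
    FeasibilityError,
    conditional_distribution,
    conditional_mle,
    gradient,
    log_likelihood,
    objective_value,
    penalty_from_paper,
    penalty_to_paper,
    suff_stats,
)

from conftest import model_implied_stats, random_dataset, random_feasible_params


class TestSuffStats:
    def test_hand_example(self):
        data = Dataset(y_z=np.array([[1.0], [-1.0]]), y_x=np.array([[2.0], [2.0]]))
        stats = suff_stats(data)
        np.testing.assert_allclose(stats.sigma_z, [[1.0]])
        np.testing.assert_allclose(stats.sigma_x, [[4.0]])
        np.testing.assert_allclose(stats.sigma_zx, [[0.0]])
        assert stats.n == 2

    def test_zero_column_gives_zero_row_col(self, rng):
        y_x = rng.standard_normal((20, 3))
        y_x[:, 1] = 0.0
        stats = suff_stats(Dataset(y_z=None, y_x=y_x))
        assert np.all(stats.sigma_x[1] == 0) and np.all(stats.sigma_x[:, 1] == 0)

    def test_matches_double_loop_oracle(self, rng):
        y_z = rng.standard_normal((50, 3))
        y_x = rng.standard_normal((50, 4))
        stats = suff_stats(Dataset(y_z=y_z, y_x=y_x))
        oracle = np.zeros((3, 4))
        for a in range(3):
            for b in range(4):
                oracle[a, b] = sum(y_z[i, a] * y_x[i, b] for i in range(50)) / 50
        np.testing.assert_allclose(stats.sigma_zx, oracle, atol=1e-12)
        oracle_z = np.zeros((3, 3))
        for a in range(3):
            for b in range(3):
                oracle_z[a, b] = sum(y_z[i, a] * y_z[i, b] for i in range(50)) / 50
        np.testing.assert_allclose(stats.sigma_z, oracle_z, atol=1e-12)

    def test_mismatched_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="row count"):
            Dataset(y_z=rng.standard_normal((5, 2)), y_x=rng.standard_normal((4, 3)))

    def test_non_finite_rejected(self):
        y = np.ones((3, 2))
        y[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            Dataset(y_z=None, y_x=y)

    def test_standardized_columns_unit_diagonal(self, rng):
        data = random_dataset(rng, n=200, m=3, p=4)
        y_z = (data.y_z - data.y_z.mean(0)) / data.y_z.std(0)
        y_x = (data.y_x - data.y_x.mean(0)) / data.y_x.std(0)
        stats = suff_stats(Dataset(y_z=y_z, y_x=y_x))
        np.testing.assert_allclose(np.diag(stats.sigma_z), 1.0, atol=1e-12)
        np.testing.assert_allclose(np.diag(stats.sigma_x), 1.0, atol=1e-12)


class TestLogLikelihood:
    def test_identity_case(self, rng):
        p = 4
        stats = suff_stats(Dataset(y_z=None, y_x=rng.standard_normal((10, p))))
        stats.sigma_x = np.eye(p)
        params = CRFParameters(s_x=np.eye(p))
        assert log_likelihood(params, stats) == pytest.approx(-p)

    def test_conditional_terms_vanish(self, rng, small_stats):
        params = random_feasible_params(rng)
        params0 = CRFParameters(
            s_x=params.s_x, l_x=params.l_x,
            s_zx=np.zeros((2, 3)), l_zx=np.zeros((2, 3)),
        )
        from lscggm.core import SufficientStats

        stats_m0 = SufficientStats(
            sigma_z=np.empty((0, 0)), sigma_x=small_stats.sigma_x,
            sigma_zx=np.empty((0, 3)), n=small_stats.n,
        )
        assert log_likelihood(params0, small_stats) == pytest.approx(
            log_likelihood(CRFParameters(s_x=params.s_x, l_x=params.l_x), stats_m0)
        )

    def test_matches_per_sample_gaussian_density(self, rng):
        """The sufficient-statistic form equals the average conditional
        Gaussian log-density up to the -(p/2) log(2 pi) constant."""
        p, m, n = 3, 2, 40
        data = random_dataset(rng, n=n, m=m, p=p)
        stats = suff_stats(data)
        params = random_feasible_params(rng, p=p, m=m)
        law = conditional_distribution(params)
        total = 0.0
        for i in range(n):
            mean = law.coefficient_map.T @ data.y_z[i]
            total += multivariate_normal.logpdf(
                data.y_x[i], mean=mean, cov=law.conditional_covariance
            )
        # the sufficient-statistic likelihood is twice the average
        # log-density plus the normalization constant
        expected = 2.0 * (total / n + 0.5 * p * np.log(2 * np.pi))
        assert log_likelihood(params, stats) == pytest.approx(expected, abs=1e-8)

    def test_infeasible_raises(self, small_stats):
        bad = CRFParameters(s_x=np.eye(3), l_x=2 * np.eye(3),
                            s_zx=np.zeros((2, 3)), l_zx=np.zeros((2, 3)))
        with pytest.raises(FeasibilityError):
            log_likelihood(bad, small_stats)


class TestGradient:
    def test_matches_finite_differences(self, rng, small_stats):
        params = random_feasible_params(rng)
        g = gradient(params, small_stats)
        eps = 1e-6

        def ll(q):
            return log_likelihood(q, small_stats)

        # symmetric block: perturb (i,j) and (j,i) together; the symmetrized
        # derivative predicts 2*g_ij for i != j and g_ii on the diagonal
        for (i, j) in [(0, 1), (2, 2)]:
            e = np.zeros((3, 3))
            e[i, j] = eps
            e[j, i] = eps
            q1 = CRFParameters(params.s_x + e, params.l_x, params.s_zx, params.l_zx)
            q2 = CRFParameters(params.s_x - e, params.l_x, params.s_zx, params.l_zx)
            fd = (ll(q1) - ll(q2)) / (2 * eps)
            expected = 2 * g.s_x[i, j] if i != j else g.s_x[i, i]
            assert fd == pytest.approx(expected, rel=1e-4)
        for (i, j) in [(0, 0), (1, 2)]:
            e = np.zeros((2, 3))
            e[i, j] = eps
            q1 = CRFParameters(params.s_x, params.l_x, params.s_zx + e, params.l_zx)
            q2 = CRFParameters(params.s_x, params.l_x, params.s_zx - e, params.l_zx)
            fd = (ll(q1) - ll(q2)) / (2 * eps)
            assert fd == pytest.approx(g.s_zx[i, j], rel=1e-4)

    def test_l_blocks_negate_s_blocks(self, rng, small_stats):
        g = gradient(random_feasible_params(rng), small_stats)
        np.testing.assert_allclose(g.l_x, -g.s_x, atol=1e-14)
        np.testing.assert_allclose(g.l_zx, -g.s_zx, atol=1e-14)

    def test_zero_at_likelihood_maximizer(self, rng):
        params = random_feasible_params(rng)
        stats = model_implied_stats(params)
        g = gradient(conditional_mle(stats), stats)
        assert np.abs(g.S).max() <= 1e-8


class TestConditionalDistribution:
    def test_zero_cross_block(self, rng):
        params = random_feasible_params(rng)
        params = CRFParameters(params.s_x, params.l_x,
                               np.zeros((2, 3)), np.zeros((2, 3)))
        law = conditional_distribution(params)
        assert np.all(law.coefficient_map == 0)
        np.testing.assert_allclose(
            law.conditional_covariance @ (params.s_x - params.l_x), np.eye(3),
            atol=1e-12,
        )

    def test_scalar_case(self):
        params = CRFParameters(s_x=np.array([[2.0]]), s_zx=np.array([[1.0]]))
        law = conditional_distribution(params)
        np.testing.assert_allclose(law.coefficient_map, [[-0.5]])
        np.testing.assert_allclose(law.conditional_covariance, [[0.5]])

    def test_matches_partitioned_marginalization(self, rng):
        """Explicit latent model (p=3, h=2, m=2): marginalizing H from the
        joint (X, H) | Z law by Schur complement must reproduce the law
        implied by the low-rank parameterization."""
        p, h, m = 3, 2, 2
        a = 0.4 * rng.standard_normal((p, h))
        m_h = np.eye(h) + 0.1 * np.ones((h, h))
        m_x = a @ np.linalg.solve(m_h, a.T) + np.eye(p) + 0.5 * np.diag(rng.random(p))
        m_zx = rng.standard_normal((m, p))
        m_zh = rng.standard_normal((m, h))
        joint = np.block([[m_x, a], [a.T, m_h]])
        assert np.linalg.eigvalsh(joint).min() > 0
        # brute-force marginal of X from the joint conditional law
        cov_joint = np.linalg.inv(joint)
        coef_joint = -cov_joint @ np.vstack([m_zx.T, m_zh.T])  # maps z -> mean(X,H)
        cov_x = cov_joint[:p, :p]
        coef_x = coef_joint[:p]  # p x m
        # low-rank parameterization
        params = CRFParameters(
            s_x=m_x,
            l_x=a @ np.linalg.solve(m_h, a.T),
            s_zx=m_zx,
            l_zx=m_zh @ np.linalg.solve(m_h, a.T),
        )
        law = conditional_distribution(params)
        np.testing.assert_allclose(law.conditional_covariance, cov_x, atol=1e-10)
        np.testing.assert_allclose(law.coefficient_map.T, coef_x, atol=1e-10)


class TestObjective:
    def test_l1_only(self, rng, small_stats):
        params = random_feasible_params(rng)
        params = CRFParameters(params.s_x, None, params.s_zx, None)
        lam = 0.3
        expected = -log_likelihood(params, small_stats) + lam * np.abs(params.S).sum()
        assert objective_value(params, small_stats, lam, 1.0) == pytest.approx(expected)

    def test_penalty_matches_svd_oracle(self, rng, small_stats):
        params = random_feasible_params(rng)
        lam, gamma = 0.2, 0.4
        _, sv, _ = np.linalg.svd(params.L)
        expected = (
            -log_likelihood(params, small_stats)
            + lam * gamma * np.abs(params.S).sum()
            + lam * (1 - gamma) * sv.sum()
        )
        assert objective_value(params, small_stats, lam, gamma) == pytest.approx(expected)

    def test_truth_maximizes_unpenalized(self, rng):
        params = random_feasible_params(rng)
        stats = model_implied_stats(params)
        base = objective_value(params, stats, 0.0, 0.5)
        for _ in range(20):
            other = random_feasible_params(rng)
            assert objective_value(other, stats, 0.0, 0.5) >= base - 1e-9

    def test_joint_convexity_on_midpoints(self, rng):
        data = random_dataset(rng, n=100, m=1, p=2)
        stats = suff_stats(data)
        lam, gamma = 0.2, 0.6
        for _ in range(200):
            p1 = random_feasible_params(rng, p=2, m=1)
            p2 = random_feasible_params(rng, p=2, m=1)
            pm = CRFParameters(
                0.5 * (p1.s_x + p2.s_x), 0.5 * (p1.l_x + p2.l_x),
                0.5 * (p1.s_zx + p2.s_zx), 0.5 * (p1.l_zx + p2.l_zx),
            )
            f1 = objective_value(p1, stats, lam, gamma)
            f2 = objective_value(p2, stats, lam, gamma)
            fm = objective_value(pm, stats, lam, gamma)
            assert fm <= 0.5 * f1 + 0.5 * f2 + 1e-9

    def test_likelihood_depends_on_difference_only(self, rng, small_stats):
        params = random_feasible_params(rng)
        delta_x = 0.3 * np.eye(3)
        delta_zx = 0.2 * np.ones((2, 3))
        shifted = CRFParameters(
            params.s_x + delta_x, params.l_x + delta_x,
            params.s_zx + delta_zx, params.l_zx + delta_zx,
        )
        assert log_likelihood(shifted, small_stats) == pytest.approx(
            log_likelihood(params, small_stats), abs=1e-10
        )


class TestPenaltyConversion:
    def test_round_trip(self):
        lam, gamma = 0.7, 0.3
        lam_n, gamma_n = penalty_to_paper(lam, gamma)
        assert (lam_n, gamma_n) == pytest.approx((0.49, 3 / 7))
        assert penalty_from_paper(lam_n, gamma_n) == pytest.approx((lam, gamma))

    def test_same_penalty_value(self, rng):
        params = random_feasible_params(rng)
        lam, gamma = 0.4, 0.6
        lam_n, gamma_n = penalty_to_paper(lam, gamma)
        v1 = lam * (gamma * np.abs(params.S).sum()
                    + (1 - gamma) * np.linalg.svd(params.L, compute_uv=False).sum())
        v2 = lam_n * (gamma_n * np.abs(params.S).sum()
                      + np.linalg.svd(params.L, compute_uv=False).sum())
        assert v1 == pytest.approx(v2)
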