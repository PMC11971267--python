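"""GGM estimation: closed forms, glasso limits, EBIC arithmetic, selection."""
import numpy as np
import pytest

import skillnet as sn
from skillnet.ggm import CorrelationMatrix, EDGE_EPS


def corr(M, n=1000, labels=None):
    M = np.asarray(M, dtype=float)
    labels = labels or tuple(f"v{i}" for i in range(M.shape[0]))
    return CorrelationMatrix(C=M, n=n, labels=labels)


def make_panel(scores, score_max=50):
    scores = np.asarray(scores, dtype=np.int64)
    labels = tuple(f"v{i}" for i in range(scores.shape[1]))
    half = scores.shape[1] // 2
    return sn.SkillPanel(
        scores=scores,
        labels=labels,
        community_of={l: ("Ls" if i < half else "Bs") for i, l in enumerate(labels)},
        score_max={l: score_max for l in labels},
    )


class TestPearsonCorrelation:
    def test_duplicated_column_is_perfectly_correlated(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 9, size=(50, 1))
        panel = make_panel(np.hstack([x, x, rng.integers(0, 9, size=(50, 1))]))
        C = sn.pearson_correlation(panel)
        assert C.C[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        panel = make_panel(rng.integers(0, 9, size=(10_000, 2)))
        C = sn.pearson_correlation(panel)
        assert abs(C.C[0, 1]) < 0.05

    def test_symmetry_and_diagonal(self, panel5000):
        C = sn.pearson_correlation(panel5000)
        np.testing.assert_array_equal(C.C, C.C.T)
        np.testing.assert_allclose(np.diag(C.C), 1.0)

    def test_constant_column_named_in_error(self):
        scores = np.ones((20, 3), dtype=np.int64)
        scores[:, 0] = np.arange(20) % 5
        scores[:, 2] = np.arange(20) % 3
        panel = make_panel(scores)
        with pytest.raises(sn.DegenerateInputError, match="v1"):
            sn.pearson_correlation(panel)


class TestUnregularizedPartials:
    def test_identity_gives_zeros(self):
        P = sn.partial_correlations_unregularized(corr(np.eye(4)))
        np.testing.assert_allclose(P - np.diag(np.diag(P)), 0.0)

    def test_equicorrelation_third(self):
        C = np.full((3, 3), 0.5); np.fill_diagonal(C, 1.0)
        P = sn.partial_correlations_unregularized(corr(C))
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert P[i, j] == pytest.approx(1 / 3, abs=1e-10)

    def test_bivariate_equals_marginal(self):
        C = np.array([[1.0, 0.6], [0.6, 1.0]])
        P = sn.partial_correlations_unregularized(corr(C))
        assert P[0, 1] == pytest.approx(0.6)

    def test_singular_matrix_advises_regularization(self):
        C = np.ones((3, 3))
        with pytest.raises(sn.DegenerateInputError, match="regularized"):
            sn.partial_correlations_unregularized(corr(C))


class TestLambdaGrid:
    def test_log_spacing_closed_form(self):
        C = np.eye(3); C[0, 1] = C[1, 0] = 0.5
        grid = sn.lambda_grid(corr(C), nlambda=3, min_ratio=0.01)
        np.testing.assert_allclose(grid, [0.5, 0.05, 0.005])

    def test_strictly_decreasing(self, panel5000):
        grid = sn.lambda_grid(sn.pearson_correlation(panel5000))
        assert (np.diff(grid) < 0).all()

    def test_constant_ratio(self):
        C = np.eye(3); C[0, 1] = C[1, 0] = 0.4
        grid = sn.lambda_grid(corr(C), nlambda=100, min_ratio=0.01)
        ratios = grid[1:] / grid[:-1]
        np.testing.assert_allclose(ratios, 0.01 ** (1 / 99))

    def test_all_zero_offdiagonal_warns(self):
        with pytest.warns(UserWarning):
            grid = sn.lambda_grid(corr(np.eye(3)))
        np.testing.assert_allclose(grid, [1e-3])


class TestGlassoFit:
    def test_large_lambda_gives_diagonal(self):
        C = np.eye(3); C[0, 1] = C[1, 0] = 0.5; C[1, 2] = C[2, 1] = 0.3
        theta = sn.glasso_fit(corr(C), lam=0.6)
        off = theta - np.diag(np.diag(theta))
        np.testing.assert_allclose(off, 0.0)

    def test_zero_lambda_matches_inverse(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(4, 40))
        S = np.corrcoef(A)
        theta = sn.glasso_fit(corr(S), lam=0.0)
        np.testing.assert_allclose(theta, np.linalg.inv(S), atol=1e-3)

    def test_output_positive_definite(self, panel5000):
        C = sn.pearson_correlation(panel5000)
        for lam in (0.3, 0.05, 0.01):
            theta = sn.glasso_fit(C, lam)
            assert np.linalg.eigvalsh(theta).min() > 0

    def test_negative_lambda_rejected(self):
        with pytest.raises(sn.ValidationError):
            sn.glasso_fit(corr(np.eye(2)), lam=-0.1)

    def test_matches_reference_solver(self, panel5000):
        """Independent route: sklearn's graphical lasso on the same input."""
        from sklearn.covariance import graphical_lasso

        C = sn.pearson_correlation(panel5000)
        for lam in (0.1, 0.03, 0.01):
            ours = sn.glasso_fit(C, lam)
            _, ref = graphical_lasso(C.C, alpha=lam, tol=1e-6, max_iter=500)
            np.testing.assert_allclose(ours, ref, atol=2e-3)


class TestEbicScore:
    def test_identity_closed_form(self):
        C = corr(np.eye(3), n=100)
        for gamma in (0.0, 0.25, 1.0):
            assert sn.ebic_score(np.eye(3), C, n=100, gamma=gamma) == pytest.approx(300.0)

    def test_single_edge_penalty_increment(self):
        """Adding one off-diagonal pair at (nearly) fixed likelihood raises
        EBIC by log(n) + 4*gamma*log(p)."""
        n, p, gamma = 100, 13, 0.25
        C = corr(np.eye(p), n=n)
        base = sn.ebic_score(np.eye(p), C, n=n, gamma=gamma)
        theta = np.eye(p)
        eps = 1e-6  # negligible likelihood change, but a counted edge
        theta[0, 1] = theta[1, 0] = eps
        with_edge = sn.ebic_score(theta, C, n=n, gamma=gamma)
        expected = np.log(n) + 4 * gamma * np.log(p)
        assert with_edge - base == pytest.approx(expected, abs=1e-4)

    def test_gamma_zero_is_plain_bic(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(4, 60)); S = np.corrcoef(A)
        theta = sn.glasso_fit(corr(S), 0.05)
        C = corr(S, n=60)
        E = np.count_nonzero(np.abs(np.triu(theta, 1)) > EDGE_EPS)
        bic_pen = sn.ebic_score(theta, C, n=60, gamma=0.0)
        ebic_pen = sn.ebic_score(theta, C, n=60, gamma=0.25)
        assert ebic_pen - bic_pen == pytest.approx(4 * 0.25 * E * np.log(4))

    def test_indefinite_theta_rejected(self):
        with pytest.raises(sn.ValidationError):
            sn.ebic_score(np.diag([1.0, -1.0]), corr(np.eye(2)), n=10, gamma=0.25)


class TestPrecisionToPcor:
    def test_diagonal_gives_empty_network(self):
        W = sn.precision_to_pcor(np.diag([2.0, 3.0, 4.0]))
        np.testing.assert_allclose(W, 0.0)

    def test_hand_arithmetic(self):
        theta = np.array([[2.0, -1.0], [-1.0, 2.0]])
        W = sn.precision_to_pcor(theta)
        assert W[0, 1] == pytest.approx(0.5)
        assert W[0, 0] == 0.0

    def test_bounded_in_open_unit_interval(self, panel5000):
        fit = sn.select_network(panel5000)
        assert np.abs(fit.W).max() < 1.0

    def test_zero_diagonal_rejected(self):
        with pytest.raises(sn.ValidationError):
            sn.precision_to_pcor(np.array([[0.0, 0.0], [0.0, 1.0]]))


class TestSelectNetwork:
    def test_defaults_carry_gamma_025(self, panel5000):
        fit = sn.select_network(panel5000)
        assert fit.gamma == 0.25

    def test_selected_lambda_is_argmin(self, panel5000):
        fit = sn.select_network(panel5000)
        assert fit.ebic_path[fit.selected_index] == fit.ebic_path.min()

    def test_identity_spec_yields_sparse_network(self):
        spec = sn.build_precision_spec(
            p=6, community_sizes=(3, 3), within_density=0.0, seed=0
        )
        hits = 0
        for seed in range(10):
            panel = sn.sample_panel(spec, 5000, seed=seed)
            if sn.select_network(panel).edge_count <= 2:
                hits += 1
        assert hits >= 9

    def test_edge_support_consistent_between_W_and_theta(self, panel5000):
        fit = sn.select_network(panel5000)
        off = ~np.eye(13, dtype=bool)
        np.testing.assert_array_equal((fit.W[off] == 0), (fit.theta[off] == 0))

    def test_path_edge_count_monotone_in_lambda(self, panel5000):
        fit = sn.select_network(panel5000)
        counts = [
            np.count_nonzero(np.abs(np.triu(t, 1)) > EDGE_EPS)
            for t in fit.theta_path
        ]
        # lambda decreases along the grid, so edge counts must not decrease
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_small_lambda_limit_matches_unregularized(self, panel5000):
        fit = sn.select_network(panel5000)
        P = sn.partial_correlations_unregularized(fit.C)
        np.fill_diagonal(P, 0.0)
        W_min = sn.precision_to_pcor(fit.theta_path[-1])
        assert np.abs(W_min - P).max() < 0.02

    def test_scale_invariance(self, default_spec):
        panel = sn.sample_panel(default_spec, 1000, seed=3)
        fit1 = sn.select_network(panel)
        scaled = sn.SkillPanel(
            scores=panel.scores * 7,
            labels=panel.labels,
            community_of=panel.community_of,
            score_max={k: v * 7 for k, v in panel.score_max.items()},
        )
        fit2 = sn.select_network(scaled)
        np.testing.assert_allclose(fit2.W, fit1.W, atol=1e-12)

    def test_deterministic_bit_identical(self, panel5000):
        f1 = sn.select_network(panel5000)
        f2 = sn.select_network(panel5000)
        np.testing.assert_array_equal(f1.W, f2.W)
        np.testing.assert_array_equal(f1.ebic_path, f2.ebic_path)
        assert f1.selected_index == f2.selected_index

    def test_n_not_above_p_rejected(self, default_spec):
        panel = sn.sample_panel(default_spec, 13, seed=0)
        with pytest.raises(sn.ValidationError, match="increase"):
            sn.select_network(panel)
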