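import numpy as np
import pytest

import lassogene as lg
from lassogene import _kernels, lasso
from oracles import lasso_bruteforce, loo_cv_bruteforce


def standardized(rng, n, m):
    X = rng.normal(size=(n, m))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return X


class TestSoftThreshold:
    @pytest.mark.parametrize("z, gamma, expected", [(5, 2, 3), (-5, 2, -3), (1, 2, 0)])
    def test_values(self, z, gamma, expected):
        assert lasso.soft_threshold(z, gamma) == expected

    def test_negative_gamma_errors(self):
        with pytest.raises(ValueError):
            lasso.soft_threshold(1.0, -0.1)


class TestLassoFit:
    def test_orthonormal_closed_form(self, rng):
        """On designs with X'X = N*I the solution is the soft-thresholded
        per-coordinate correlation."""
        n, m = 64, 6
        Q, _ = np.linalg.qr(rng.normal(size=(n, m)))
        X = Q * np.sqrt(n)
        y = rng.normal(size=n)
        for lam in (0.01, 0.05, 0.2):
            beta = lasso.lasso_fit(X, y, lam)
            closed = np.array([lasso.soft_threshold(X[:, j] @ y / n, lam) for j in range(m)])
            np.testing.assert_allclose(beta, closed, atol=1e-6)

    def test_lambda_max_gives_zero(self, rng):
        X = standardized(rng, 50, 5)
        y = rng.normal(size=50)
        y -= y.mean()
        lmax = lasso.lambda_max(X, y)
        assert np.all(lasso.lasso_fit(X, y, lmax) == 0.0)
        assert np.all(lasso.lasso_fit(X, y, 2 * lmax) == 0.0)

    def test_zero_penalty_equals_least_squares(self, rng):
        X = standardized(rng, 40, 4)
        y = rng.normal(size=40)
        y -= y.mean()
        beta = lasso.lasso_fit(X, y, 0.0, tol=1e-12)
        ols = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(beta, ols, rtol=1e-6, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_bruteforce_solver(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 30, 8
        X = standardized(rng, n, m)
        y = X[:, 0] * 0.8 + rng.normal(size=n)
        y -= y.mean()
        for lam in (0.02, 0.1, 0.3):
            beta = lasso.lasso_fit(X, y, lam)
            ref = lasso_bruteforce(X, y, lam)
            np.testing.assert_allclose(beta, ref, atol=1e-6)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_sklearn_lasso(self, seed):
        # scikit-learn's Lasso minimizes the identical (1/(2N)) objective
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(seed)
        n, m = 80, 7
        X = standardized(rng, n, m)
        y = X @ rng.normal(size=m) * 0.4 + rng.normal(size=n)
        y -= y.mean()
        lam = 0.2 * lasso.lambda_max(X, y)
        beta = lasso.lasso_fit(X, y, lam)
        ref = Lasso(alpha=lam, fit_intercept=False, tol=1e-12, max_iter=50_000).fit(X, y).coef_
        np.testing.assert_allclose(beta, ref, atol=1e-6)

    def test_kkt_conditions_at_solution(self, rng):
        for _ in range(10):
            n, m = 60, 10
            X = standardized(rng, n, m)
            y = X @ rng.normal(size=m) * 0.3 + rng.normal(size=n)
            y -= y.mean()
            lam = 0.1 * lasso.lambda_max(X, y)
            beta = lasso.lasso_fit(X, y, lam)
            assert lasso.kkt_violation(X, y, beta, lam) < 1e-5

    def test_objective_nonincreasing_over_sweeps(self, rng):
        n, m = 50, 8
        X = standardized(rng, n, m)
        y = rng.normal(size=n)
        y -= y.mean()
        lam = 0.05
        gram, xty = X.T @ X, X.T @ y

        def objective(b):
            r = y - X @ b
            return r @ r / (2 * n) + lam * np.abs(b).sum()

        beta = np.zeros(m)
        vals = [objective(beta)]
        for _ in range(15):
            _kernels.cd_solve(gram, xty, n, lam, beta, 0.0, 1)
            vals.append(objective(beta))
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_scale_consistency(self, rng):
        # scaling y by c and lambda by c scales the solution by c
        X = standardized(rng, 40, 5)
        y = rng.normal(size=40)
        y -= y.mean()
        lam, c = 0.08, 3.7
        b1 = lasso.lasso_fit(X, y, lam)
        b2 = lasso.lasso_fit(X, c * y, c * lam)
        np.testing.assert_allclose(b2, c * b1, atol=1e-8)

    def test_nonconvergence_raises_with_kkt(self, rng):
        X = standardized(rng, 30, 5)
        y = rng.normal(size=30)
        y -= y.mean()
        with pytest.raises(lasso.ConvergenceError) as exc:
            lasso.lasso_fit(X, y, 0.01, tol=0.0, max_iter=2)
        assert exc.value.kkt_violation >= 0.0


class TestLambdaPath:
    def test_shape_first_point_and_monotone(self, rng):
        X = standardized(rng, 50, 6)
        y = rng.normal(size=50)
        y -= y.mean()
        path = lasso.lambda_path(X, y, n_points=100)
        assert path.size == 100
        assert np.all(np.diff(path) < 0)
        assert np.all(lasso.lasso_fit(X, y, path[0]) == 0.0)

    def test_orthogonal_response_single_point(self, rng):
        X = standardized(rng, 20, 3)
        y = np.zeros(20)
        path = lasso.lambda_path(X, y)
        assert path.tolist() == [0.0]

    def test_support_size_envelope_grows_along_path(self):
        """Across simulated genes, the support-size envelope is non-decreasing
        as the penalty shrinks (rare drop-and-re-entry is allowed per gene)."""
        sizes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cfg = lg.SimConfig(seed=seed, n_subjects=120, genes=[("G", 8)], causal=[("G", 2, 0.5)])
            G = lg.simulate_genotypes(cfg)
            y = 0.5 * (G.dosages[:, 2] - G.dosages[:, 2].mean()) + rng.normal(size=120)
            Z, _, _, const = lasso.standardize_columns(G.dosages)
            Z = Z[:, ~const]
            y = y - y.mean()
            path = lasso.lambda_path(Z, y, n_points=40)
            betas = _kernels.cd_path(Z.T @ Z, Z.T @ y, 120, path, 1e-7, 10_000)
            sizes.append((betas != 0).sum(axis=1))
        envelope = np.max(np.array(sizes), axis=0)
        assert np.all(np.diff(envelope) >= 0)


class TestCvSelectLambda:
    def test_noiseless_signal_recovers_column(self, rng):
        n = 60
        X = standardized(rng, n, 5)
        y = X[:, 2].copy()
        lam_star, cv = lasso.cv_select_lambda(X, y)
        path = lasso.lambda_path(X, y)
        assert lam_star == path[-1]  # smallest path point wins without noise
        beta = lasso.lasso_fit(X, y, lam_star)
        assert beta[2] != 0.0

    def test_matches_bruteforce_cv_oracle(self):
        rng = np.random.default_rng(7)
        n, m = 24, 4
        X = standardized(rng, n, m)
        y = rng.normal(size=n)
        y -= y.mean()
        lambdas = lasso.lambda_path(X, y, n_points=8)
        _, cv = lasso.cv_select_lambda(X, y, lambdas=lambdas)
        ref = loo_cv_bruteforce(X, y, lambdas)
        np.testing.assert_allclose(cv, ref, atol=1e-8)

    def test_tie_prefers_larger_lambda(self, rng):
        X = standardized(rng, 30, 4)
        y = rng.normal(size=30)
        y -= y.mean()
        lmax = lasso.lambda_max(X, y)
        # both path points exceed lambda_max: identical all-zero fits, equal CV error
        lam_star, cv = lasso.cv_select_lambda(X, y, lambdas=np.array([3 * lmax, 2 * lmax]))
        assert cv[0] == cv[1]
        assert lam_star == 3 * lmax

    def test_kfold_seeded_and_too_few_samples(self, rng):
        X = standardized(rng, 30, 4)
        y = rng.normal(size=30)
        y -= y.mean()
        a = lasso.cv_select_lambda(X, y, n_folds=5, seed=3)
        b = lasso.cv_select_lambda(X, y, n_folds=5, seed=3)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1], b[1])
        with pytest.raises(ValueError):
            lasso.cv_select_lambda(X[:2], y[:2])


class TestSelectSnps:
    def test_overwhelming_signal_selected(self):
        cfg = lg.SimConfig(
            seed=9, n_subjects=200, genes=[("G", 1)], causal=[("G", 0, 1.0)], noise_sd=0.1
        )
        G = lg.simulate_genotypes(cfg)
        P, _ = lg.simulate_phenotype(G, cfg)
        fit = lg.select_snps(G.dosages, P.phenotype - P.phenotype.mean())
        assert fit.selected.tolist() == [0]

    def test_null_selection_frequently_empty(self):
        empty = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cfg = lg.SimConfig(seed=seed, n_subjects=100, genes=[("G", 10)])
            G = lg.simulate_genotypes(cfg)
            y = rng.normal(size=100)
            fit = lg.select_snps(G.dosages, y)
            empty += fit.n_selected == 0
        assert empty >= 5  # LOO-CV usually backs off to the null model

    def test_duplicate_columns_lowest_index_wins(self, rng):
        n = 120
        g = np.asarray(np.random.default_rng(1).binomial(2, 0.3, size=n), dtype=float)
        X = np.column_stack([g, g, rng.binomial(2, 0.3, size=n).astype(float)])
        y = 0.8 * (g - g.mean()) + rng.normal(size=n) * 0.3
        fit = lg.select_snps(X, y - y.mean())
        assert 0 in fit.selected
        assert 1 not in fit.selected

    def test_constant_columns_dropped_all_constant_empty(self, rng):
        X = np.column_stack([np.ones(50), np.zeros(50)])
        fit = lg.select_snps(X, rng.normal(size=50))
        assert fit.n_selected == 0
        assert fit.dropped_constant == [0, 1]

    def test_coefficients_on_dosage_scale(self):
        # noiseless linear phenotype: back-transformed coefficient recovers slope
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.4, size=400).astype(float)
        y = 0.7 * g
        fit = lg.select_snps(g.reshape(-1, 1), y - y.mean())
        assert fit.beta[0] == pytest.approx(0.7, rel=0.05)
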