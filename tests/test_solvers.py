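import numpy as np
import pytest
from sklearn.linear_model import Lasso

from misonet.solvers import (
    CvConfig,
    cocolasso_fit,
    covariance_lasso_fit,
    covariance_objective,
    cv_lambda_path,
    grouped_lasso_fit,
    grouped_lambda_max,
    grouped_objective,
    hmlasso_fit,
    pairwise_moments,
    psd_project_maxnorm,
    psd_project_weighted_frobenius,
    sgl_lambda_max,
    sgl_objective,
    sparse_group_lasso_fit,
    stacked_lasso_fit,
    stacked_lambda_max,
    stacked_objective,
    standardize,
    adaptive_gamma,
)
from misonet.solvers.sgl import SglCvKernel, SparseGroupProblem
from misonet.solvers.standardize import SolverError

from oracles import group_lasso_bcd, minimize_split, sdp_maxnorm_project


def _design(n, p, seed, sparsity=3, noise=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = np.zeros(p)
    beta[:sparsity] = rng.uniform(0.5, 1.5, sparsity) * rng.choice([-1, 1], sparsity)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y - y.mean(), beta


class TestStandardize:
    def test_already_standardized_unchanged(self):
        X, y, _ = _design(50, 4, 0)
        Xs, ys, rec = standardize(X, y + 0.0)
        assert np.allclose(Xs, X, atol=1e-12)

    def test_constant_column_dropped(self):
        X, y, _ = _design(30, 3, 1)
        X = np.column_stack([X, np.ones(30)])
        Xs, ys, rec = standardize(X, y)
        assert Xs.shape[1] == 3
        assert list(rec.kept) == [0, 1, 2]

    def test_back_transform_matches_raw_ols(self):
        rng = np.random.default_rng(2)
        X = rng.normal(loc=5, scale=[1, 3, 0.5], size=(40, 3))
        y = 2.0 + X @ np.array([1.0, -0.5, 2.0]) + 0.1 * rng.normal(size=40)
        Xs, ys, rec = standardize(X, y)
        beta_std, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        beta, intercept = rec.back_transform(beta_std)
        A = np.column_stack([np.ones(40), X])
        direct = np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.allclose(np.concatenate([[intercept], beta]), direct, atol=1e-8)


class TestAdaptiveGamma:
    @pytest.mark.parametrize("p,n,expected", [(100, 10000, 3), (10, 1000, 2)])
    def test_closed_form_values(self, p, n, expected):
        assert adaptive_gamma(p, n) == expected

    def test_p_equal_n_rejected(self):
        with pytest.raises(SolverError):
            adaptive_gamma(100, 100)


class TestSparseGroupLasso:
    def _problem(self, lam, alpha=0.5, n=30, p=6, seed=3):
        X, y, _ = _design(n, p, seed)
        groups = [("a", X[:, : p // 2]), ("b", X[:, p // 2:])]
        return SparseGroupProblem(y, groups, alpha, lam), X, y

    def test_lambda_zero_recovers_ols(self):
        prob, X, y = self._problem(0.0)
        beta = sparse_group_lasso_fit(prob)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(beta, ols, atol=1e-6)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_lambda_max_gives_all_zero(self, alpha):
        prob, X, y = self._problem(0.0, alpha)
        lam_max = sgl_lambda_max(y, prob.X_groups, alpha)
        beta = sparse_group_lasso_fit(
            SparseGroupProblem(y, prob.X_groups, alpha, lam_max * 1.0001)
        )
        assert np.all(beta == 0.0)
        beta2 = sparse_group_lasso_fit(
            SparseGroupProblem(y, prob.X_groups, alpha, lam_max * 0.98)
        )
        assert np.any(beta2 != 0.0)

    def test_alpha_one_matches_sklearn_lasso(self):
        X, y, _ = _design(60, 8, 4)
        lam = 0.08 * len(y)
        prob = SparseGroupProblem(y, [("a", X[:, :4]), ("b", X[:, 4:])], 1.0, lam)
        beta = sparse_group_lasso_fit(prob)
        sk = Lasso(alpha=lam / len(y), fit_intercept=False, tol=1e-14, max_iter=500000).fit(X, y)
        assert np.allclose(beta, sk.coef_, atol=1e-6)

    def test_alpha_zero_matches_group_lasso_oracle(self):
        X, y, _ = _design(50, 6, 5)
        lam = 2.0
        groups = [X[:, :3], X[:, 3:]]
        prob = SparseGroupProblem(y, [("a", groups[0]), ("b", groups[1])], 0.0, lam)
        beta = sparse_group_lasso_fit(prob)
        oracle = group_lasso_bcd(y, groups, lam)
        assert np.allclose(beta, oracle, atol=1e-6)

    def test_objective_matches_direct_minimization(self):
        prob, X, y = self._problem(3.0, alpha=0.5)
        beta = sparse_group_lasso_fit(prob)
        f_impl = sgl_objective(prob, beta)
        p = X.shape[1]
        smooth = lambda b: 0.5 * float(np.sum((y - X @ b) ** 2))
        l1 = 0.5 * 3.0 * np.ones(p)
        gterms = [(0.5 * 3.0 * np.sqrt(3), np.arange(3)), (0.5 * 3.0 * np.sqrt(3), np.arange(3, 6))]
        _, f_oracle = minimize_split((smooth, l1, gterms), p, [np.zeros(p), beta])
        assert abs(f_impl - f_oracle) <= 1e-6

    def test_objective_not_increased_from_warm_starts(self):
        prob, X, y = self._problem(1.0)
        rng = np.random.default_rng(6)
        for _ in range(3):
            b0 = rng.normal(size=6)
            beta = sparse_group_lasso_fit(prob, beta0=b0)
            assert sgl_objective(prob, beta) <= sgl_objective(prob, b0) + 1e-12


class TestStackedLasso:
    def test_single_copy_equals_plain_lasso(self):
        X, y, _ = _design(40, 5, 7)
        beta = stacked_lasso_fit([X], [y], 0.1)
        sk = Lasso(alpha=0.1, fit_intercept=False, tol=1e-14, max_iter=500000).fit(X, y)
        assert np.allclose(beta, sk.coef_, atol=1e-8)

    def test_identical_copies_cancel(self):
        X, y, _ = _design(40, 5, 8)
        b1 = stacked_lasso_fit([X], [y], 0.15)
        b3 = stacked_lasso_fit([X, X, X], [y, y, y], 0.15)
        assert np.allclose(b1, b3, atol=1e-10)

    def test_adaptive_weights_silence_noise_variables(self):
        X, y, beta_true = _design(80, 8, 9, sparsity=2, noise=0.3)
        beta = stacked_lasso_fit([X], [y], 0.05, adaptive=True)
        noise_vars = np.flatnonzero(beta_true == 0)
        assert np.all(beta[noise_vars] == 0.0)
        assert np.any(beta[:2] != 0.0)

    def test_objective_matches_direct_minimization(self):
        rng = np.random.default_rng(10)
        n, p, D = 30, 5, 3
        X_list = [np.asarray((lambda A: (A - A.mean(0)) / A.std(0))(rng.normal(size=(n, p)))) for _ in range(D)]
        y_list = [rng.normal(size=n) for _ in range(D)]
        lam = 0.1
        beta = stacked_lasso_fit(X_list, y_list, lam)
        f_impl = stacked_objective(X_list, y_list, beta, lam)
        smooth = lambda b: sum(
            float(np.sum((y - X @ b) ** 2)) for X, y in zip(X_list, y_list)
        ) / (2 * n * D)
        _, f_oracle = minimize_split((smooth, lam * np.ones(p), []), p, [np.zeros(p), beta])
        assert abs(f_impl - f_oracle) <= 1e-6

    def test_lambda_max_zeroes_solution(self):
        X, y, _ = _design(40, 5, 11)
        lam_max = stacked_lambda_max([X], [y])
        assert np.all(stacked_lasso_fit([X], [y], lam_max * 1.0001) == 0.0)


class TestGroupedLasso:
    def _copies(self, seed=12, n=40, p=5, D=3, jitter=0.05):
        rng = np.random.default_rng(seed)
        X, y, _ = _design(n, p, seed)
        X_list, y_list = [], []
        for _ in range(D):
            Xd = X + jitter * rng.normal(size=X.shape)
            Xd = (Xd - Xd.mean(0)) / Xd.std(0)
            X_list.append(Xd)
            y_list.append(y + jitter * rng.normal(size=n))
        return X_list, y_list

    def test_identical_copies_match_stacked_support_and_values(self):
        X, y, _ = _design(40, 5, 13)
        D = 3
        fit = grouped_lasso_fit([X] * D, [y] * D, 0.12 * np.sqrt(D))
        b1 = stacked_lasso_fit([X], [y], 0.12)
        assert np.allclose(fit.betas - fit.betas[0], 0.0, atol=1e-12)
        assert np.allclose(fit.betas[0], b1, atol=1e-8)

    def test_shared_support_exact_across_copies(self):
        X_list, y_list = self._copies()
        for lam in (0.02, 0.1, 0.3):
            fit = grouped_lasso_fit(X_list, y_list, lam)
            zero_pattern = fit.betas == 0.0
            for d in range(1, len(X_list)):
                assert np.array_equal(zero_pattern[0], zero_pattern[d])

    def test_lambda_max_all_zero(self):
        X_list, y_list = self._copies(seed=14)
        lam_max = grouped_lambda_max(X_list, y_list)
        fit = grouped_lasso_fit(X_list, y_list, lam_max * 1.0001)
        assert np.all(fit.betas == 0.0)

    def test_objective_matches_direct_minimization(self):
        X_list, y_list = self._copies(seed=15, n=30, p=4, D=3)
        lam = 0.08
        fit = grouped_lasso_fit(X_list, y_list, lam)
        f_impl = grouped_objective(X_list, y_list, fit.betas, lam)
        n, p = X_list[0].shape
        D = len(X_list)
        smooth = lambda b: sum(
            float(np.sum((y - X @ b.reshape(D, p)[d]) ** 2))
            for d, (X, y) in enumerate(zip(X_list, y_list))
        ) / (2 * n)
        gterms = [(lam, np.arange(j, D * p, p)) for j in range(p)]
        _, f_oracle = minimize_split(
            (smooth, np.zeros(D * p), gterms), D * p,
            [np.zeros(D * p), fit.betas.reshape(-1)],
        )
        assert abs(f_impl - f_oracle) <= 1e-6


class TestPairwiseMoments:
    def test_complete_data_equals_gram(self):
        X, y, _ = _design(25, 4, 16)
        est = pairwise_moments(X, y)
        assert np.allclose(est.S_pair, X.T @ X / 25, atol=1e-12)
        assert np.allclose(est.rho_pair, X.T @ y / 25, atol=1e-12)
        assert np.allclose(est.R, 1.0)

    def test_staggered_missingness_matches_explicit_loop(self):
        X = np.array([
            [1.0, np.nan, 2.0],
            [np.nan, 1.0, 0.5],
            [2.0, 3.0, np.nan],
            [0.5, 1.5, 1.0],
        ])
        y = np.array([1.0, 2.0, np.nan, 0.5])
        est = pairwise_moments(X, y)
        p = X.shape[1]
        for j in range(p):
            for k in range(p):
                rows = [i for i in range(4) if not np.isnan(X[i, j]) and not np.isnan(X[i, k])]
                expect = np.mean([X[i, j] * X[i, k] for i in rows]) if rows else 0.0
                assert est.S_pair[j, k] == pytest.approx(expect)
                assert est.n_jk[j, k] == len(rows)
            rows_y = [i for i in range(4) if not np.isnan(X[i, j]) and not np.isnan(y[i])]
            expect_r = np.mean([X[i, j] * y[i] for i in rows_y]) if rows_y else 0.0
            assert est.rho_pair[j] == pytest.approx(expect_r)

    def test_r_diagonal_is_observed_fraction(self):
        X, y, _ = _design(20, 3, 17)
        X[:5, 0] = np.nan
        est = pairwise_moments(X, y)
        assert est.R[0, 0] == pytest.approx(0.75)
        assert est.R[1, 1] == pytest.approx(1.0)

    def test_fully_missing_column_rejected(self):
        X = np.full((5, 2), np.nan)
        X[:, 1] = 1.0
        with pytest.raises(SolverError):
            pairwise_moments(X, np.ones(5))


class TestPsdProjections:
    def test_psd_input_unchanged(self):
        rng = np.random.default_rng(18)
        A = rng.normal(size=(6, 6))
        S = A @ A.T / 6
        assert np.allclose(psd_project_maxnorm(S), S, atol=1e-8)
        assert np.allclose(psd_project_weighted_frobenius(S), S, atol=1e-8)

    def test_unweighted_frobenius_equals_eigenvalue_clipping(self):
        rng = np.random.default_rng(19)
        for _ in range(5):
            A = rng.normal(size=(8, 8))
            S = (A + A.T) / 2
            got = psd_project_weighted_frobenius(S)
            w, V = np.linalg.eigh(S)
            clip = (V * np.maximum(w, 0)) @ V.T
            assert np.abs(got - clip).max() < 1e-6

    def test_maxnorm_two_by_two_matches_sdp(self):
        S = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        got = psd_project_maxnorm(S)
        assert np.linalg.eigvalsh(got).min() >= -1e-8
        _, oracle_dist = sdp_maxnorm_project(S)
        assert np.abs(got - S).max() <= oracle_dist + 1e-4

    def test_projections_idempotent(self):
        rng = np.random.default_rng(20)
        A = rng.normal(size=(5, 5))
        S = (A + A.T) / 2
        P1 = psd_project_maxnorm(S)
        assert np.abs(psd_project_maxnorm(P1) - P1).max() < 1e-5
        P2 = psd_project_weighted_frobenius(S)
        assert np.abs(psd_project_weighted_frobenius(P2) - P2).max() < 1e-5


class TestCovarianceLasso:
    def test_identity_sigma_soft_thresholds(self):
        rho = np.array([0.8, -0.3, 0.05])
        beta = covariance_lasso_fit(np.eye(3), rho, 0.1)
        assert np.allclose(beta, [0.7, -0.2, 0.0], atol=1e-10)

    def test_complete_pipeline_equals_plain_lasso(self):
        X, y, _ = _design(50, 6, 21)
        est = pairwise_moments(X, y)
        Sigma = psd_project_weighted_frobenius(est.S_pair)
        beta = covariance_lasso_fit(Sigma, est.rho_pair, 0.08)
        sk = Lasso(alpha=0.08, fit_intercept=False, tol=1e-14, max_iter=500000).fit(X, y)
        assert np.allclose(beta, sk.coef_, atol=1e-6)

    def test_lambda_above_rho_max_all_zero(self):
        X, y, _ = _design(30, 4, 22)
        est = pairwise_moments(X, y)
        lam = np.abs(est.rho_pair).max() * 1.0001
        assert np.all(covariance_lasso_fit(est.S_pair, est.rho_pair, lam) == 0.0)

    def test_objective_matches_direct_minimization(self):
        X, y, _ = _design(40, 5, 23)
        X[np.random.default_rng(23).random(X.shape) < 0.2] = np.nan
        Xs, ys, _ = standardize(X, y)
        est = pairwise_moments(Xs, ys)
        Sigma = psd_project_maxnorm(est.S_pair)
        lam = 0.05
        beta = covariance_lasso_fit(Sigma, est.rho_pair, lam)
        f_impl = covariance_objective(Sigma, est.rho_pair, beta, lam)
        smooth = lambda b: 0.5 * float(b @ Sigma @ b) - float(est.rho_pair @ b)
        _, f_oracle = minimize_split((smooth, lam * np.ones(5), []), 5, [np.zeros(5), beta])
        assert abs(f_impl - f_oracle) <= 1e-6


class TestCocoHmLasso:
    def test_complete_data_collapse_to_same_model(self):
        X, y, _ = _design(60, 8, 24)
        cfg = CvConfig(lambda_min_ratio=1e-1, seed=5)
        a = cocolasso_fit(X, y, cfg)
        b = hmlasso_fit(X, y, cfg)
        ba = np.array([a.coefficients[k] for k in sorted(a.coefficients)])
        bb = np.array([b.coefficients[k] for k in sorted(b.coefficients)])
        assert np.allclose(ba, bb, atol=1e-10)
        assert a.lambda_chosen == b.lambda_chosen

    def test_hmlasso_alpha_from_grid(self):
        X, y, _ = _design(50, 5, 25)
        rng = np.random.default_rng(25)
        X[rng.random(X.shape) < 0.3] = np.nan
        cfg = CvConfig(lambda_min_ratio=1e-1, seed=6)
        fit = hmlasso_fit(X, y, cfg)
        assert fit.extra_hyperparams["alpha_weight"] in cfg.alpha_weight_grid

    def test_deterministic_given_seed(self):
        X, y, _ = _design(50, 5, 26)
        rng = np.random.default_rng(26)
        X[rng.random(X.shape) < 0.2] = np.nan
        cfg = CvConfig(lambda_min_ratio=1e-1, seed=7)
        a = cocolasso_fit(X, y, cfg)
        b = cocolasso_fit(X, y, cfg)
        assert a.coefficients == b.coefficients
        assert a.lambda_chosen == b.lambda_chosen

    def test_all_missing_predictor_raises_inside_moments(self):
        X, y, _ = _design(30, 3, 27)
        X[:, 1] = np.nan
        with pytest.raises(SolverError):
            pairwise_moments(X, y)


class TestCvLambdaPath:
    def test_grid_shape_and_endpoints(self):
        X, y, _ = _design(60, 6, 28)
        kernel = SglCvKernel(y, [("a", X)], alpha=1.0)
        cfg = CvConfig(n_lambda=50, lambda_min_ratio=1e-2, seed=1)
        grid, errs, lam = cv_lambda_path(kernel, 60, cfg)
        assert len(grid) == 50 and len(errs) == 50
        assert np.all(np.diff(grid) < 0)
        assert grid[-1] == pytest.approx(grid[0] * 1e-2)

    def test_empty_model_at_lambda_max_on_every_fold(self):
        X, y, _ = _design(60, 6, 29)
        kernel = SglCvKernel(y, [("a", X)], alpha=1.0)
        cfg = CvConfig(seed=2, lambda_min_ratio=1e-2)
        grid, _, _ = cv_lambda_path(kernel, 60, cfg)
        from misonet.solvers.cv import make_folds

        folds = make_folds(60, 5, 2)
        for val in folds:
            tr = np.setdiff1d(np.arange(60), val)
            beta = kernel.fit_path(tr, np.array([grid[0]]))[0]
            assert np.all(beta == 0.0)

    def test_cv_minimum_interior_for_well_specified_problem(self):
        X, y, _ = _design(100, 10, 30, sparsity=3, noise=0.5)
        kernel = SglCvKernel(y, [("a", X)], alpha=1.0)
        cfg = CvConfig(seed=3, lambda_min_ratio=1e-4)
        grid, errs, lam = cv_lambda_path(kernel, 100, cfg)
        k = int(np.argmin(errs))
        assert 0 < k < len(grid) - 1
        # exhaustive check: chosen lambda minimizes the mean CV curve
        assert lam == grid[np.argmin(errs)]

    def test_too_few_samples_rejected(self):
        X, y, _ = _design(10, 3, 31)
        kernel = SglCvKernel(y, [("a", X)], alpha=1.0)
        with pytest.raises(ValueError):
            cv_lambda_path(kernel, 3, CvConfig(n_folds=5))
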