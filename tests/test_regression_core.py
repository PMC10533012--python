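import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from milasso import regression_core as rc


def brute_force_lasso(X, y, lam, tol=1e-12):
    """Oracle: the LASSO as a smooth bound-constrained problem on the
    positive/negative coefficient split, solved with L-BFGS-B."""
    from scipy.optimize import minimize

    n, p = X.shape

    def fun(ab):
        beta = ab[:p] - ab[p:]
        r = y - X @ beta
        g = -X.T @ r / n
        return float(r @ r) / (2 * n) + lam * ab.sum(), np.concatenate([g + lam, -g + lam])

    res = minimize(fun, np.zeros(2 * p), jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * 2 * p,
                   options={"maxiter": 20000, "ftol": tol, "gtol": 1e-12})
    return res.x[:p] - res.x[p:]


def _random_problem(rng, n=30, p=5, snr=1.0):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p) * (rng.random(p) < 0.6)
    y = X @ beta + rng.normal(size=n) / snr
    return rc.zscore(X), rc.center(y)


class TestStandardization:
    def test_zscore_simple_column(self):
        d = rc.zscore(np.array([[2.0], [4.0], [6.0]]))
        np.testing.assert_allclose(d.X[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_column_dropped(self):
        d = rc.zscore(np.column_stack([np.ones(5), np.arange(5.0)]))
        assert d.dropped.tolist() == [0] and d.kept.tolist() == [1]

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            rc.zscore(np.ones((4, 2)))

    def test_random_matrix_moments(self):
        rng = np.random.default_rng(0)
        d = rc.zscore(rng.normal(size=(50, 10)) * 7 + 3)
        assert np.abs(d.X.mean(axis=0)).max() < 1e-10
        assert np.abs(d.X.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_center_examples(self):
        np.testing.assert_allclose(rc.center(np.array([1.0, 2.0, 3.0])).y, [-1, 0, 1])
        assert np.all(rc.center(np.full(4, 3.3)).y == 0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_centered_mean_is_zero(self, seed):
        y = np.random.default_rng(seed).normal(size=17) * 100
        assert abs(rc.center(y).y.mean()) < 1e-12


class TestCoordinateDescent:
    def test_lambda_above_max_gives_empty_support(self):
        rng = np.random.default_rng(1)
        d, yc = _random_problem(rng)
        lmax = rc.lambda_max(d, yc)
        fit = rc.lasso_cd(d, yc, lmax * 1.0000001)
        assert fit.support.size == 0

    def test_lambda_zero_matches_ols(self):
        rng = np.random.default_rng(2)
        d, yc = _random_problem(rng)
        fit = rc.lasso_cd(d, yc, 0.0, tol=1e-12)
        ols = np.linalg.lstsq(d.X, yc.y, rcond=None)[0]
        np.testing.assert_allclose(fit.coef, ols, atol=1e-8)

    def test_orthonormal_design_soft_threshold(self):
        rng = np.random.default_rng(3)
        n, p = 64, 6
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = Q * np.sqrt(n)  # X'X = n I
        y = rng.normal(size=n)
        yc = rc.center(y)
        d = rc.StandardizedDesign(X, np.zeros(p), np.ones(p), np.arange(p), np.array([], int))
        lam = 0.05
        fit = rc.lasso_cd(d, yc, lam, tol=1e-14)
        b_ols = X.T @ yc.y / n
        expected = np.sign(b_ols) * np.maximum(np.abs(b_ols) - lam, 0.0)
        np.testing.assert_allclose(fit.coef, expected, atol=1e-12)

    def test_kkt_certificate_and_oracle_objective(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            d, yc = _random_problem(rng)
            lam = 10.0 ** rng.uniform(-3, -0.5)
            fit = rc.lasso_cd(d, yc, lam)
            assert rc.kkt_residual(d, yc, fit) < 1e-6
            b = brute_force_lasso(d.X, yc.y, lam)
            assert fit.objective <= rc.lasso_objective(d.X, yc.y, b, lam) + 1e-6

    def test_invalid_args_rejected(self):
        rng = np.random.default_rng(5)
        d, yc = _random_problem(rng)
        with pytest.raises(ValueError):
            rc.lasso_cd(d, yc, -0.1)
        with pytest.raises(ValueError):
            rc.lasso_cd(d, yc, 0.1, tol=0.0)


class TestLambdaPath:
    def test_log_spaced_grid(self):
        rng = np.random.default_rng(6)
        d, yc = _random_problem(rng)
        grid = rc.lambda_path(d, yc, 3, 0.01)
        lmax = rc.lambda_max(d, yc)
        np.testing.assert_allclose(grid, [lmax, 0.1 * lmax, 0.01 * lmax])

    def test_first_grid_point_gives_zero_fit(self):
        rng = np.random.default_rng(7)
        d, yc = _random_problem(rng)
        path = rc.fit_path(d, yc, rc.lambda_path(d, yc, 20, 1e-2))
        assert path.fits[0].support.size == 0
        assert path.fits[-1].support.size >= path.fits[0].support.size

    def test_warm_start_no_worse_than_cold(self):
        rng = np.random.default_rng(8)
        d, yc = _random_problem(rng)
        grid = rc.lambda_path(d, yc, 30, 1e-3)
        path = rc.fit_path(d, yc, grid)
        for lam, f in zip(grid, path.fits):
            cold = rc.lasso_cd(d, yc, lam)
            assert f.objective <= cold.objective + 1e-7

    def test_objective_nonincreasing_along_iterations(self):
        # one coordinate sweep can never increase the objective: check via
        # successively tighter iteration caps
        rng = np.random.default_rng(9)
        d, yc = _random_problem(rng)
        lam = 0.05
        objs = [rc.lasso_cd(d, yc, lam, tol=1e-15, max_iter=k).objective
                for k in (1, 2, 4, 8, 16, 32)]
        assert all(a >= b - 1e-12 for a, b in zip(objs, objs[1:]))


class TestCrossValidation:
    def test_null_signal_cv_mse_near_variance(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(300, 4))
        y = rng.normal(size=300)
        grid = np.array([10.0, 1.0])
        mse, se = rc.cv_lasso(X, y, grid, folds=5, seed=0)
        assert mse[0] == pytest.approx(np.var(y), rel=0.15)

    def test_identical_seed_identical_curve(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 6))
        y = X[:, 0] + rng.normal(size=60)
        grid = rc.lambda_path(rc.zscore(X), rc.center(y), 10, 1e-2)
        a = rc.cv_lasso(X, y, grid, folds=5, seed=5)
        b = rc.cv_lasso(X, y, grid, folds=5, seed=5)
        np.testing.assert_array_equal(a[0], b[0])

    def test_signal_beats_lambda_max(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(100, 5))
        y = 3.0 * X[:, 2] + rng.normal(size=100) * 0.5
        grid = rc.lambda_path(rc.zscore(X), rc.center(y), 30, 1e-3)
        mse, _ = rc.cv_lasso(X, y, grid, folds=5, seed=1)
        assert mse[-5:].min() < mse[0] * 0.3

    def test_too_small_folds_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            rc.cv_lasso(X, X[:, 0], np.array([1.0, 0.1]), folds=1, seed=0)


def _path_with(lambdas, coefs, cv_mse=None, cv_se=None):
    fits = [rc.LassoFit(l, 0.0, np.asarray(c, float), 0.0, 1, True)
            for l, c in zip(lambdas, coefs)]
    return rc.LassoPath(np.asarray(lambdas, float), fits,
                        None if cv_mse is None else np.asarray(cv_mse, float),
                        None if cv_se is None else np.asarray(cv_se, float))


class TestLambdaSelection:
    def test_min_mse_picks_smallest_error(self):
        path = _path_with([1.0, 0.5, 0.1], [[0], [1], [1]], [3.0, 1.0, 2.0], [0.1] * 3)
        assert rc.select_lambda(path, "min_mse").lam == 0.5

    def test_one_se_picks_larger_lambda_within_band(self):
        path = _path_with([1.0, 0.5, 0.1], [[0], [1], [1]], [1.4, 1.0, 1.1], [0.2, 0.5, 0.3])
        assert rc.select_lambda(path, "one_se").lam == 1.0

    def test_one_se_never_below_min_mse(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(80, 8))
        y = X[:, 0] - X[:, 3] + rng.normal(size=80) * 0.3
        d, yc = rc.zscore(X), rc.center(y)
        grid = rc.lambda_path(d, yc, 40, 1e-3)
        path = rc.fit_path(d, yc, grid)
        path.cv_mse, path.cv_se = rc.cv_lasso(X, y, grid, folds=5, seed=2)
        assert (rc.select_lambda(path, "one_se").lam
                >= rc.select_lambda(path, "min_mse").lam)

    def test_noblocking_picks_smallest_lambda_with_zero_block(self):
        # blocking column 0: zero for lambda >= 0.3, nonzero below
        path = _path_with(
            [1.0, 0.5, 0.3, 0.1],
            [[0.0, 0.0], [0.0, 1.0], [0.0, 2.0], [0.5, 2.0]],
        )
        sel = rc.select_lambda(path, "noblocking", blocking_columns=[0])
        assert sel.lam == 0.3
        assert 0 not in sel.support

    def test_noblocking_all_nonzero_returns_lambda_max_with_warning(self):
        path = _path_with([1.0, 0.5, 0.1], [[0.0], [0.4], [0.9]], None, None)
        sel = rc.select_lambda(path, "noblocking", blocking_columns=[0])
        assert sel.lam == 1.0 and sel.warning is not None

    def test_noblocking_requires_blocking_set(self):
        path = _path_with([1.0, 0.5], [[0], [1]])
        with pytest.raises(ValueError, match="blocking"):
            rc.select_lambda(path, "noblocking", blocking_columns=[])

    def test_noblocking_support_never_contains_blocking(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(60, 6))
        X[:, 5] = (rng.random(60) < 0.5).astype(float)  # dummy-ish column
        y = X[:, 0] + 0.3 * X[:, 5] + rng.normal(size=60) * 0.4
        d, yc = rc.zscore(X), rc.center(y)
        path = rc.fit_path(d, yc, rc.lambda_path(d, yc, 50, 1e-3))
        sel = rc.select_lambda(path, "noblocking", blocking_columns=[5])
        assert 5 not in sel.support


class TestSklearnCrossCheck:
    def test_matches_sklearn_lasso(self):
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(15)
        d, yc = _random_problem(rng, n=60, p=8)
        for lam in (0.3, 0.05, 0.01):
            ours = rc.lasso_cd(d, yc, lam, tol=1e-12)
            ref = sklearn_linear.Lasso(alpha=lam, fit_intercept=False,
                                       tol=1e-12, max_iter=100000).fit(d.X, yc.y)
            np.testing.assert_allclose(ours.coef, ref.coef_, atol=1e-6)
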