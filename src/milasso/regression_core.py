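"""Standardization, coordinate-descent LASSO, lambda path, CV, and the
three lambda-selection criteria (MinMSE, 1SE, NoBlocking).

The LASSO objective is

    (1/(2n)) * sum_i (y_i - B0 - sum_j B_j x_ij)^2 + lambda * sum_j |B_j|

fit on z-scored predictors and a mean-centered response, so the intercept
(B0 = mean of y) is never penalized.  Minimization is cyclic coordinate
descent with covariance (Gram) updates, an active-set strategy, and warm
starts along a descending log-spaced lambda grid, as in glmnet.

The NoBlocking criterion is the novel selection rule: the smallest grid
lambda at which every blocking (data-origin) dummy has an exactly-zero
coefficient — the most permissive model that still excludes all
fixed-effect dummies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 100_000


# --------------------------------------------------------------------------
# standardization
# --------------------------------------------------------------------------

@dataclass
class StandardizedDesign:
    """Z-scored predictor matrix (sample SD, n-1 denominator).

    Zero-variance columns are dropped and recorded in ``dropped``;
    ``kept`` maps retained columns back to the original indices.
    """

    X: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    kept: np.ndarray
    dropped: np.ndarray
    columns: list[str] | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class CenteredResponse:
    y: np.ndarray
    mean: float


def zscore(X: np.ndarray, columns: list[str] | None = None) -> StandardizedDesign:
    """Per-column z-score normalization, (x - mean)/sd with sample SD."""
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with n >= 2")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(sds > 0)
    dropped = np.flatnonzero(sds == 0)
    if kept.size == 0:
        raise ValueError("all columns are zero-variance")
    if dropped.size:
        names = [columns[j] for j in dropped] if columns else dropped.tolist()
        log.info("dropping %d zero-variance column(s): %s", dropped.size, names)
    Z = (X[:, kept] - means[kept]) / sds[kept]
    kept_cols = [columns[j] for j in kept] if columns else None
    return StandardizedDesign(Z, means[kept], sds[kept], kept, dropped, kept_cols)


def center(y: np.ndarray) -> CenteredResponse:
    """Mean-center the response; the stored mean is the unpenalized intercept."""
    y = np.asarray(y, float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("need a 1-D response with n >= 2")
    mu = float(y.mean())
    return CenteredResponse(y - mu, mu)


# --------------------------------------------------------------------------
# coordinate descent
# --------------------------------------------------------------------------

@dataclass
class LassoFit:
    lam: float
    intercept: float
    coef: np.ndarray
    objective: float
    iterations: int
    converged: bool

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.coef != 0.0)


def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def _cd_kernel(G, g0, diag, lam, beta, tol, max_iter):
    """Inner coordinate-descent loop (plain-Python reference; a compiled
    version replaces it below when numba is available).

    Maintains the gradient ``grad = g0 - G @ beta`` incrementally so a
    sweep over coordinates whose coefficients do not move costs O(1)
    per coordinate; alternates full sweeps with sweeps over the active
    set until a full sweep moves nothing by more than ``tol``.
    """
    p = beta.size
    grad = g0 - G @ beta
    it = 0
    converged = False
    full_sweep = True
    active = np.where(beta != 0.0)[0]
    while it < max_iter:
        it += 1
        delta_max = 0.0
        n_idx = p if full_sweep else active.size
        for k in range(n_idx):
            j = k if full_sweep else active[k]
            bj = beta[j]
            z = grad[j] + diag[j] * bj
            if z > lam:
                bn = (z - lam) / diag[j]
            elif z < -lam:
                bn = (z + lam) / diag[j]
            else:
                bn = 0.0
            if bn != bj:
                d = bn - bj
                beta[j] = bn
                for q in range(p):  # G is symmetric: row access is contiguous
                    grad[q] -= G[j, q] * d
                step = abs(d)
                if step > delta_max:
                    delta_max = step
        if full_sweep:
            active = np.where(beta != 0.0)[0]
            if delta_max < tol:
                converged = True
                break
            full_sweep = False
        elif delta_max < tol:
            full_sweep = True  # active set stable; verify with a full sweep
    return it, converged


try:  # compiled kernel: same algorithm, same results, much faster sweeps
    from numba import njit

    _cd_kernel = njit(cache=True, fastmath=False)(_cd_kernel)  # type: ignore[assignment]
except ImportError:  # pragma: no cover - numba is an optional accelerator
    pass


def lasso_objective(X: np.ndarray, y: np.ndarray, coef: np.ndarray, lam: float) -> float:
    r = y - X @ coef
    n = y.size
    return float(r @ r) / (2.0 * n) + lam * float(np.abs(coef).sum())


def _cd_solve(
    G: np.ndarray,
    g0: np.ndarray,
    diag: np.ndarray,
    lam: float,
    beta: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, int, bool]:
    """Coordinate descent on the Gram form (``G = X'X/n``, ``g0 = X'y/n``)."""
    G = np.ascontiguousarray(G, dtype=np.float64)
    g0 = np.ascontiguousarray(g0, dtype=np.float64)
    diag = np.ascontiguousarray(diag, dtype=np.float64)
    beta = np.ascontiguousarray(beta, dtype=np.float64)
    it, converged = _cd_kernel(G, g0, diag, float(lam), beta, float(tol), int(max_iter))
    return beta, it, converged


def lasso_cd(
    design: StandardizedDesign,
    y: CenteredResponse | np.ndarray,
    lam: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    warm_start: np.ndarray | None = None,
    _gram: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> LassoFit:
    """Solve the LASSO at one penalty by cyclic coordinate descent."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    yc = y if isinstance(y, CenteredResponse) else center(np.asarray(y, float))
    X = design.X
    n = X.shape[0]
    if _gram is None:
        G = X.T @ X / n
        g0 = X.T @ yc.y / n
        diag = np.diag(G).copy()
    else:
        G, g0, diag = _gram
    beta = np.zeros(X.shape[1]) if warm_start is None else warm_start.astype(float).copy()
    beta, it, converged = _cd_solve(G, g0, diag, lam, beta, tol, max_iter)
    if not converged:
        log.warning("lasso_cd: max_iter=%d reached at lambda=%.4g", max_iter, lam)
    obj = lasso_objective(X, yc.y, beta, lam)
    return LassoFit(lam, yc.mean, beta, obj, it, converged)


def kkt_residual(design: StandardizedDesign, y: CenteredResponse | np.ndarray,
                 fit: LassoFit) -> float:
    """Max violation of the LASSO stationarity conditions: for zero
    coefficients |x_j'r/n| <= lambda, for nonzero ones x_j'r/n =
    lambda*sign(b_j)."""
    yc = y if isinstance(y, CenteredResponse) else center(np.asarray(y, float))
    r = yc.y - design.X @ fit.coef
    g = design.X.T @ r / design.n
    viol = np.where(
        fit.coef != 0.0,
        np.abs(g - fit.lam * np.sign(fit.coef)),
        np.maximum(np.abs(g) - fit.lam, 0.0),
    )
    return float(viol.max()) if viol.size else 0.0


# --------------------------------------------------------------------------
# lambda path and cross-validation
# --------------------------------------------------------------------------

@dataclass
class LassoPath:
    lambdas: np.ndarray
    fits: list[LassoFit]
    cv_mse: np.ndarray | None = None
    cv_se: np.ndarray | None = None

    def fit_at(self, lam: float) -> LassoFit:
        j = int(np.argmin(np.abs(self.lambdas - lam)))
        if not np.isclose(self.lambdas[j], lam):
            raise ValueError(f"lambda {lam} not on the grid")
        return self.fits[j]


def lambda_max(design: StandardizedDesign, y: CenteredResponse | np.ndarray) -> float:
    yc = y if isinstance(y, CenteredResponse) else center(np.asarray(y, float))
    return float(np.abs(design.X.T @ yc.y).max() / design.n)


def lambda_path(
    design: StandardizedDesign,
    y: CenteredResponse | np.ndarray,
    n_lambda: int = 100,
    ratio: float = 1e-3,
) -> np.ndarray:
    """Log-spaced descending grid from lambda_max down to ratio*lambda_max."""
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    if not (0.0 < ratio < 1.0):
        raise ValueError("ratio must be in (0, 1)")
    lmax = lambda_max(design, y)
    if lmax == 0.0:
        lmax = 1.0  # y orthogonal to X; grid is arbitrary, all fits are zero
    return lmax * np.logspace(0.0, np.log10(ratio), n_lambda)


def fit_path(
    design: StandardizedDesign,
    y: CenteredResponse | np.ndarray,
    lambdas: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> LassoPath:
    """Fit the whole grid with warm starts (largest lambda first)."""
    yc = y if isinstance(y, CenteredResponse) else center(np.asarray(y, float))
    lambdas = np.asarray(lambdas, float)
    if np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda grid must be strictly decreasing")
    X = design.X
    n = X.shape[0]
    gram = (X.T @ X / n, X.T @ yc.y / n, (X**2).sum(axis=0) / n)
    fits = []
    beta = np.zeros(X.shape[1])
    for lam in lambdas:
        f = lasso_cd(design, yc, lam, tol, max_iter, warm_start=beta, _gram=gram)
        beta = f.coef
        fits.append(f)
    return LassoPath(lambdas, fits)


def _fold_indices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[i::folds] for i in range(folds)]


def cv_lasso(
    X_raw: np.ndarray,
    y_raw: np.ndarray,
    lambdas: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray]:
    """K-fold CV curve over a lambda grid.

    Standardization and centering are re-estimated on the training folds
    only; held-out predictions are made on the response's original scale.
    Returns (mean MSE, SE of MSE) per lambda, SE = SD of fold MSEs /
    sqrt(folds).
    """
    X_raw = np.asarray(X_raw, float)
    y_raw = np.asarray(y_raw, float)
    n = X_raw.shape[0]
    if folds < 2 or n < folds:
        raise ValueError("need 2 <= folds <= n")
    rng = np.random.default_rng(seed)
    fold_mse = np.empty((folds, len(lambdas)))
    for k, test_idx in enumerate(_fold_indices(n, folds, rng)):
        if n - test_idx.size < 2 or test_idx.size < 1:
            raise ValueError(f"fold {k} leaves fewer than 2 training observations")
        train = np.setdiff1d(np.arange(n), test_idx)
        d_tr = zscore(X_raw[train])
        y_tr = center(y_raw[train])
        path = fit_path(d_tr, y_tr, lambdas, tol, max_iter)
        X_te = (X_raw[np.ix_(test_idx, d_tr.kept)] - d_tr.means) / d_tr.sds
        for j, f in enumerate(path.fits):
            pred = X_te @ f.coef + y_tr.mean
            fold_mse[k, j] = float(np.mean((y_raw[test_idx] - pred) ** 2))
    mse = fold_mse.mean(axis=0)
    se = fold_mse.std(axis=0, ddof=1) / np.sqrt(folds)
    return mse, se


def cv_path(
    X_raw: np.ndarray,
    y_raw: np.ndarray,
    n_lambda: int = 100,
    ratio: float = 1e-3,
    folds: int = 10,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[StandardizedDesign, CenteredResponse, LassoPath]:
    """Full-data path plus CV curve (the grid comes from the full data)."""
    design = zscore(X_raw)
    yc = center(y_raw)
    grid = lambda_path(design, yc, n_lambda, ratio)
    path = fit_path(design, yc, grid, tol, max_iter)
    path.cv_mse, path.cv_se = cv_lasso(
        X_raw[:, design.kept], y_raw, grid, folds, seed, tol, max_iter
    )
    return design, yc, path


# --------------------------------------------------------------------------
# lambda selection
# --------------------------------------------------------------------------

CRITERIA = ("min_mse", "one_se", "noblocking")


@dataclass
class LambdaSelection:
    criterion: str
    lam: float
    support: np.ndarray
    coef: np.ndarray
    warning: str | None = None


def select_lambda(
    path: LassoPath,
    criterion: str,
    blocking_columns: np.ndarray | list[int] | None = None,
) -> LambdaSelection:
    """Pick a lambda from a fitted path under one of the three criteria.

    * ``min_mse``: smallest mean CV error (ties -> larger lambda).
    * ``one_se``: largest lambda with CV error within one SE of the minimum.
    * ``noblocking``: smallest grid lambda whose fit zeroes every blocking
      dummy; scans the coefficient path only (no CV needed).
    """
    lambdas = path.lambdas
    if criterion in {"min_mse", "one_se"}:
        if path.cv_mse is None:
            raise ValueError(f"criterion {criterion!r} needs a CV curve")
        mse = path.cv_mse
        i_min = int(np.argmin(mse))  # argmin: first = largest lambda on ties
        if criterion == "min_mse":
            lam = lambdas[i_min]
            fit = path.fits[i_min]
            return LambdaSelection("min_mse", lam, fit.support, fit.coef)
        thr = mse[i_min] + path.cv_se[i_min]
        i_sel = int(np.flatnonzero(mse <= thr)[0])  # grid descends: first = largest
        fit = path.fits[i_sel]
        return LambdaSelection("one_se", lambdas[i_sel], fit.support, fit.coef)
    if criterion == "noblocking":
        if blocking_columns is None or len(blocking_columns) == 0:
            raise ValueError("noblocking criterion needs a nonempty blocking set")
        blk = np.asarray(blocking_columns, int)
        zero_blk = [bool(np.all(f.coef[blk] == 0.0)) for f in path.fits]
        warning = None
        if not np.all(np.diff(np.asarray(zero_blk, int)) <= 0):
            warning = "blocking coefficients re-enter non-monotonically along the path"
            log.info("noblocking: %s", warning)
        idx = np.flatnonzero(zero_blk)
        if idx.size == 0 or (idx.size == 1 and idx[0] == 0 and len(lambdas) > 1):
            fit = path.fits[0]
            warning = "blocking coefficients nonzero at every lambda below lambda_max"
            log.warning("noblocking: %s", warning)
            return LambdaSelection("noblocking", lambdas[0], fit.support, fit.coef, warning)
        i_sel = int(idx[-1])  # smallest lambda with an all-zero blocking block
        fit = path.fits[i_sel]
        return LambdaSelection("noblocking", lambdas[i_sel], fit.support, fit.coef, warning)
    raise ValueError(f"unknown criterion {criterion!r}; expected one of {CRITERIA}")
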