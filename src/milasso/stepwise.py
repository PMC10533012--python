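"""Stepwise linear regression with pairwise interactions on raw-scale data.

The procedure starts from the full candidate model (or its largest
full-rank subset) and alternates single-term moves: first try to remove
the in-model term with the largest partial-F p-value above ``premove``,
otherwise add the out-of-model term with the smallest p-value below
``penter``. A removal-step F test on a single column equals the squared
t statistic of that coefficient; an addition step's F comes from the SSE
drop of appending the column. Interactions are element-wise products of
raw columns and are not forced to keep their main effects in the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_PENTER = 0.05
DEFAULT_PREMOVE = 0.10
DEFAULT_MAX_STEPS = 500

INTERACTION_SEP = ":"


@dataclass(frozen=True)
class TermSet:
    """Candidate pool: main effects plus unordered pairwise interactions."""

    mains: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.mains)) != len(self.mains):
            raise ValueError("duplicate main effects")
        canon = [tuple(sorted(p)) for p in self.interactions]
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate interactions")

    @property
    def names(self) -> list[str]:
        return list(self.mains) + [interaction_name(a, b) for a, b in self.interactions]

    def __len__(self) -> int:
        return len(self.mains) + len(self.interactions)


def interaction_name(a: str, b: str) -> str:
    a, b = sorted((a, b))
    return f"{a}{INTERACTION_SEP}{b}"


def parse_term(name: str) -> tuple[str, ...]:
    """Variables making up a term name ('a:b' -> ('a','b'))."""
    return tuple(name.split(INTERACTION_SEP))


def build_terms(candidates: list[str]) -> TermSet:
    """All candidates as mains plus every unordered pair as an interaction."""
    if not candidates:
        raise ValueError("need at least one candidate")
    mains = tuple(dict.fromkeys(candidates))
    inters = tuple(
        (mains[i], mains[j])
        for i in range(len(mains))
        for j in range(i + 1, len(mains))
    )
    return TermSet(mains, inters)


def term_columns(data: pd.DataFrame, pool: TermSet) -> pd.DataFrame:
    """Design columns for a term pool, raw scale; interactions as products."""
    cols = {}
    for v in pool.mains:
        cols[v] = data[v].to_numpy(float)
    for a, b in pool.interactions:
        cols[interaction_name(a, b)] = data[a].to_numpy(float) * data[b].to_numpy(float)
    return pd.DataFrame(cols, index=data.index)


@dataclass
class FitResult:
    """OLS fit of a fixed term set, with per-term inference."""

    terms: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    pvalue: dict[str, float]
    adj_r2: float
    r2: float
    sigma2: float
    n: int
    steps: list[str] = field(default_factory=list)


def ols_fit(Xcols: pd.DataFrame, y: np.ndarray, terms: list[str]) -> FitResult:
    """OLS with intercept on the given term columns; two-sided t tests."""
    n = len(y)
    X = np.column_stack([np.ones(n)] + [Xcols[t].to_numpy() for t in terms])
    k = X.shape[1]
    if np.linalg.matrix_rank(X) < k:
        raise np.linalg.LinAlgError(f"rank-deficient design for terms {terms}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - k
    sse = float(resid @ resid)
    sigma2 = sse / df if df > 0 else np.nan
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(sigma2 * np.diag(XtX_inv), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df) if df > 0 else np.ones(k)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / df if df > 0 else np.nan
    names = ["(Intercept)"] + terms
    return FitResult(
        terms=list(terms),
        coef=dict(zip(names, beta)),
        se=dict(zip(names, se)),
        pvalue=dict(zip(names, pvals)),
        adj_r2=adj,
        r2=r2,
        sigma2=sigma2,
        n=n,
    )


def _sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


MIN_START_DF = 10  # residual df below which start-from-full p-values collapse


def _full_rank_start(
    Xcols: pd.DataFrame, y: np.ndarray, pool: TermSet, log_steps: list[str]
) -> list[str]:
    """Starting model: the full candidate pool when it is full rank and
    leaves enough residual df for its F tests to carry information; a
    ridge-screened full-rank subset when the pool fits but is collinear;
    otherwise forward selection from the intercept-only model (a
    saturated start has ~zero residual SSE, so every p-value collapses
    and no term could ever be pruned)."""
    n = len(y)
    names = pool.names
    limit = n - 1 - MIN_START_DF
    if len(names) > limit or limit < 1:
        log_steps.append(
            f"full start would leave residual df < {MIN_START_DF}; "
            "forward selection from intercept only"
        )
        log.info("stepwise: %s", log_steps[-1])
        return []
    X = np.column_stack([np.ones(n)] + [Xcols[t].to_numpy() for t in names])
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return list(names)
    # rank-deficient pool: keep the strongest full-rank subset under a
    # light ridge screen on z-scored columns, mains before interactions
    Z = Xcols[names].to_numpy(float)
    sd = Z.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (Z - Z.mean(axis=0)) / sd
    A = Z.T @ Z + 1e-3 * n * np.eye(len(names))
    b = np.linalg.solve(A, Z.T @ (y - y.mean()))
    order = np.argsort(-np.abs(b), kind="stable")
    mains = set(pool.mains)
    ranked = [names[i] for i in order]
    ranked = [t for t in ranked if t in mains] + [t for t in ranked if t not in mains]
    kept: list[str] = []
    X = np.ones((n, 1))
    for t in ranked:
        if len(kept) >= limit:
            break
        cand = np.column_stack([X, Xcols[t].to_numpy()])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            X = cand
            kept.append(t)
    log_steps.append(
        f"rank-deficient full start: kept {len(kept)} of {len(names)} term(s) (ridge screen)"
    )
    log.info("stepwise: %s", log_steps[-1])
    return [t for t in names if t in set(kept)]


def stepwise_fit(
    data: pd.DataFrame,
    y: np.ndarray | pd.Series,
    pool: TermSet,
    penter: float = DEFAULT_PENTER,
    premove: float = DEFAULT_PREMOVE,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> FitResult:
    """Start-from-full stepwise selection with partial-F add/remove tests."""
    if not (0.0 < penter <= premove < 1.0):
        raise ValueError("need 0 < penter <= premove < 1")
    y = np.asarray(y, float)
    n = len(y)
    Xcols = term_columns(data, pool)
    steps: list[str] = []
    current = _full_rank_start(Xcols, y, pool, steps)
    all_terms = pool.names
    seen_models: set[frozenset] = set()
    best_sse_for_size: dict[int, float] = {}

    def design(terms: list[str]) -> np.ndarray:
        return np.column_stack([np.ones(n)] + [Xcols[t].to_numpy() for t in terms])

    for _ in range(max_steps):
        key = frozenset(current)
        if key in seen_models:
            steps.append("model revisited; stopping")
            break
        seen_models.add(key)
        moved = False

        # ---- removal: largest p-value above premove
        if current:
            fit = ols_fit(Xcols, y, current)
            pv = {t: fit.pvalue[t] for t in current}
            worst = sorted(pv, key=lambda t: (-pv[t], t))[0]
            if pv[worst] > premove or fit.n - len(current) - 1 <= 0:
                current = [t for t in current if t != worst]
                steps.append(f"remove {worst} (p={pv[worst]:.4g})")
                moved = True
        if not moved:
            # ---- addition: smallest p-value below penter
            out = [t for t in all_terms if t not in current]
            if out:
                X = design(current)
                k = X.shape[1]
                df2 = n - k - 1
                if df2 > 0:
                    Q, _ = np.linalg.qr(X)
                    r = y - Q @ (Q.T @ y)
                    sse0 = float(r @ r)
                    best_t, best_p = None, np.inf
                    for t in sorted(out):
                        z = Xcols[t].to_numpy()
                        zt = z - Q @ (Q.T @ z)
                        zz = float(zt @ zt)
                        if zz <= 1e-10 * float(z @ z) + 1e-300:
                            continue  # collinear with current model
                        ssdrop = float(r @ zt) ** 2 / zz
                        sse1 = sse0 - ssdrop
                        if sse1 <= 0:
                            p = 0.0
                        else:
                            F = ssdrop / (sse1 / df2)
                            p = float(stats.f.sf(F, 1, df2))
                        if p < best_p - 1e-15:
                            best_t, best_p = t, p
                    if best_t is not None and best_p < penter:
                        new = current + [best_t]
                        new_sse = _sse(design(new), y)
                        prev = best_sse_for_size.get(len(new))
                        if prev is None or new_sse < prev - 1e-12:
                            best_sse_for_size[len(new)] = new_sse
                            current = new
                            steps.append(f"add {best_t} (p={best_p:.4g})")
                            moved = True
                        else:
                            steps.append(f"blocked re-add of {best_t} (no SSE improvement)")
        if not moved:
            break
    else:
        log.warning("stepwise: max_steps=%d reached", max_steps)

    order = [t for t in all_terms if t in set(current)]
    result = ols_fit(Xcols, y, order)
    result.steps = steps
    return result
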