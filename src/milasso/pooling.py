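"""Rubin's-rule pooling of per-imputation fits and cross-imputation
term selection.

For each term the pooled estimate is the mean across imputations, the
within-imputation variance W is the mean squared standard error, the
between-imputation variance B is the sample variance of the estimates,
and the total variance is

    T = W + (1 + 1/m) * B

with pooled SD = sqrt(T).  p-values are summarized by their mean +- SD
and an 80% trimmed mean; a term is flagged ``primary`` when the mean
p-value is <= 0.05 and ``secondary`` when the trimmed mean is (the
dagger in the report tables).  A term absent from an imputation's model
contributes estimate 0, SE 0 and p-value 1, so presence across
imputations is what the summaries weigh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from milasso.stepwise import FitResult

P_FLAG_LEVEL = 0.05
DEFAULT_RETAIN = 0.8


def rubin_total_variance(W: float, B: float, m: int) -> float:
    """Total variance T = W + (1 + 1/m) * B."""
    if m < 2:
        raise ValueError("Rubin's rule needs m >= 2 imputations")
    if W < 0 or B < 0:
        raise ValueError("variance components must be >= 0")
    return W + (1.0 + 1.0 / m) * B


def trimmed_mean(values, retain: float = DEFAULT_RETAIN) -> float:
    """Mean after dropping floor(((1-retain)/2)*n) values from each tail."""
    v = np.sort(np.asarray(values, float))
    if v.size == 0:
        raise ValueError("empty list")
    if not (0.0 < retain <= 1.0):
        raise ValueError("retain must be in (0, 1]")
    # tiny epsilon so e.g. (1-0.8)/2*10 = 0.999... still drops one per tail
    k = int(np.floor((1.0 - retain) / 2.0 * v.size + 1e-9))
    return float(v[k : v.size - k].mean())


@dataclass
class PooledTerm:
    term: str
    estimate: float
    W: float
    B: float
    T: float
    pooled_sd: float
    p_mean: float
    p_sd: float
    p_trimmed: float
    presence: int
    primary: bool
    secondary: bool


@dataclass
class PooledModel:
    response: str
    terms: list[PooledTerm]
    adj_r2_mean: float
    adj_r2_sd: float
    m: int

    def term(self, name: str) -> PooledTerm:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)

    @property
    def term_names(self) -> list[str]:
        return [t.term for t in self.terms]


def pool_fits(
    fits: list[FitResult],
    response: str = "y",
    retain: float = DEFAULT_RETAIN,
) -> PooledModel:
    """Pool m per-imputation OLS fits into one summary per term."""
    m = len(fits)
    if m < 2:
        raise ValueError("need fits from m >= 2 imputations")
    all_terms: list[str] = ["(Intercept)"]
    for f in fits:
        for t in f.terms:
            if t not in all_terms:
                all_terms.append(t)

    pooled = []
    for t in all_terms:
        est = np.array([f.coef.get(t, 0.0) for f in fits])
        ses = np.array([f.se.get(t, 0.0) for f in fits])
        pvs = np.array([f.pvalue.get(t, 1.0) for f in fits])
        W = float(np.mean(ses**2))
        B = float(np.var(est, ddof=1))
        T = rubin_total_variance(W, B, m)
        p_mean = float(pvs.mean())
        p_trim = trimmed_mean(pvs, retain)
        pooled.append(
            PooledTerm(
                term=t,
                estimate=float(est.mean()),
                W=W,
                B=B,
                T=T,
                pooled_sd=float(np.sqrt(T)),
                p_mean=p_mean,
                p_sd=float(pvs.std(ddof=1)),
                p_trimmed=p_trim,
                presence=sum(1 for f in fits if t == "(Intercept)" or t in f.terms),
                primary=p_mean <= P_FLAG_LEVEL,
                secondary=p_trim <= P_FLAG_LEVEL,
            )
        )
    adj = np.array([f.adj_r2 for f in fits], float)
    return PooledModel(
        response=response,
        terms=pooled,
        adj_r2_mean=float(np.nanmean(adj)),
        adj_r2_sd=float(np.nanstd(adj, ddof=1)),
        m=m,
    )


def model_to_dict(model: PooledModel) -> dict:
    """JSON-serializable form of a pooled model (for run artifacts)."""
    return {
        "response": model.response,
        "m": model.m,
        "adj_r2_mean": model.adj_r2_mean,
        "adj_r2_sd": model.adj_r2_sd,
        "terms": [vars(t).copy() for t in model.terms],
    }


def model_from_dict(d: dict) -> PooledModel:
    return PooledModel(
        response=d["response"],
        terms=[PooledTerm(**t) for t in d["terms"]],
        adj_r2_mean=d["adj_r2_mean"],
        adj_r2_sd=d["adj_r2_sd"],
        m=d["m"],
    )


def select_terms(
    coefficient_lists: dict[str, np.ndarray | list[float]],
    retain: float = DEFAULT_RETAIN,
) -> list[str]:
    """Terms whose 80% trimmed mean of |coefficient| across imputations is
    positive — i.e. terms that survive in enough imputations that trimming
    cannot zero them out. Absent-in-an-imputation coefficients enter as 0,
    so a term kept (even hugely) in only one of ten imputations is
    excluded."""
    selected = []
    for term, coefs in coefficient_lists.items():
        if trimmed_mean(np.abs(np.asarray(coefs, float)), retain) > 0.0:
            selected.append(term)
    return selected
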