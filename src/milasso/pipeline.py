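"""Pipeline orchestration: two LASSO rounds, two stepwise rounds,
Rubin's-rule pooling, and publication-style report tables.

Stage order, per response (responses are modelled independently):

1. round-1 LASSO per imputation on all predictors (incl. blocking
   dummies and derived k-day averages); lambda chosen under MinMSE, 1SE
   and NoBlocking; per criterion a variable survives if its 80% trimmed
   mean |standardized coefficient| across imputations is positive; the
   union over the three criteria is the stepwise candidate set.
2. round-1 stepwise per imputation on the raw-scale candidates and all
   their pairwise interactions; a census counts term occurrences.
3. round-2 LASSO per imputation on the census terms (interaction
   columns built as raw products, then z-scored) plus the blocking
   dummies, lambda under NoBlocking; surviving terms by the same
   trimmed-|coefficient| rule.  Final candidate mains are the variables
   appearing in the surviving set individually or inside a surviving
   interaction; final candidate interactions are the surviving ones.
4. round-2 stepwise per imputation on that pool; fits pooled with
   Rubin's rule into the reported model.

In round 2 any term involving a blocking dummy is counted as part of
the blocking block, so origin fixed effects can never re-enter the
final models through an interaction.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from milasso import features, pooling, regression_core as rc, stepwise as sw
from milasso.config import config_hash, default_config
from milasso.data_model import BoundsTable, DatasetTable, VariableMeta
from milasso.imputation import ImputedStack, draw_imputations
from milasso.pooling import PooledModel

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# per-imputation design construction
# --------------------------------------------------------------------------

def sync_temporal_scalars(table: DatasetTable, metas: list[VariableMeta]) -> DatasetTable:
    """Overwrite each temporal variable's scalar cell with the (possibly
    imputed) series value on the collection day, keeping the two
    representations of the harvest-day value consistent."""
    out = table.copy()
    for m in metas:
        if not m.temporal:
            continue
        wide = out.series_wide(m.name)
        for obs in out.values.index:
            if obs in wide.index:
                day = int(out.collection_day.loc[obs])
                if day in wide.columns and pd.notna(wide.at[obs, day]):
                    out.values.at[obs, m.name] = wide.at[obs, day]
    return out


@dataclass
class ImputationDesign:
    """Raw-scale analysis frame for one completed dataset."""

    frame: pd.DataFrame           # predictors + derived averages + dummies
    responses: pd.DataFrame
    predictor_columns: list[str]  # frame column order
    blocking_columns: list[str]


def build_designs(stack: ImputedStack, metas: list[VariableMeta]) -> list[ImputationDesign]:
    """Per-imputation design frames with temporal averages recomputed
    after filling the daily series."""
    designs = []
    resp_names = [m.name for m in metas if m.role == "response"]
    for t in stack:
        t = sync_temporal_scalars(t, metas)
        enc = features.add_temporal_averages(t, metas)
        pred = [m.name for m in enc.metas if m.role in {"predictor", "blocking_dummy"}]
        blocking = [m.name for m in enc.metas if m.role == "blocking_dummy"]
        designs.append(
            ImputationDesign(
                frame=enc.table.values[pred].astype(float),
                responses=enc.table.values[resp_names].astype(float),
                predictor_columns=pred,
                blocking_columns=blocking,
            )
        )
    return designs


def _stage_seed(seed: int, *indices: int) -> int:
    s = seed & 0x7FFFFFFF
    for i in indices:
        s = (s * 1_000_003 + i * 97 + 17) % (2**31)
    return s


# --------------------------------------------------------------------------
# round 1
# --------------------------------------------------------------------------

@dataclass
class RoundOneResult:
    criterion_sets: dict[str, list[str]]     # per criterion, selected variables
    candidates: list[str]                    # union fed to stepwise
    lambdas: dict[str, list[float]]          # per criterion, lambda per imputation
    skipped: bool = False


def run_round1_lasso(
    designs: list[ImputationDesign],
    response: str,
    cfg: dict,
    seed: int,
    resp_index: int = 0,
) -> RoundOneResult:
    """First LASSO screen: per-imputation CV paths, three lambda criteria,
    cross-imputation trimmed-|coefficient| selection, union of criteria."""
    lcfg, retain = cfg["lasso"], cfg["pooling"]["retain"]
    cols = designs[0].predictor_columns
    coefs = {c: {v: [] for v in cols} for c in rc.CRITERIA}
    lambdas: dict[str, list[float]] = {c: [] for c in rc.CRITERIA}
    any_rows = False
    for i, d in enumerate(designs):
        y = d.responses[response]
        keep = y.notna()
        if keep.sum() < max(2, cfg["cv"]["folds"]):
            continue
        any_rows = True
        X = d.frame.loc[keep].to_numpy(float)
        yv = y[keep].to_numpy(float)
        design = rc.zscore(X, columns=cols)
        yc = rc.center(yv)
        grid = rc.lambda_path(design, yc, lcfg["n_lambda"], lcfg["ratio"])
        path = rc.fit_path(design, yc, grid, lcfg["tol"], lcfg["max_iter"])
        path.cv_mse, path.cv_se = rc.cv_lasso(
            X[:, design.kept], yv, grid, cfg["cv"]["folds"],
            _stage_seed(seed, resp_index, i), lcfg["tol"], lcfg["max_iter"],
        )
        blk = np.array(
            [j for j, name in enumerate(design.columns) if name in d.blocking_columns],
            int,
        )
        for crit in rc.CRITERIA:
            if crit == "noblocking" and blk.size == 0:
                lambdas[crit].append(np.nan)
                for v in cols:
                    coefs[crit][v].append(0.0)
                continue
            sel = rc.select_lambda(path, crit, blocking_columns=blk)
            lambdas[crit].append(float(sel.lam))
            chosen = dict(zip(design.columns, sel.coef))
            for v in cols:
                coefs[crit][v].append(chosen.get(v, 0.0))
    if not any_rows:
        log.warning("response %s has too few observed values; skipped", response)
        return RoundOneResult({c: [] for c in rc.CRITERIA}, [], lambdas, skipped=True)

    criterion_sets = {}
    for crit in rc.CRITERIA:
        selected = pooling.select_terms(coefs[crit], retain)
        if crit == "noblocking":
            selected = [v for v in selected if v not in designs[0].blocking_columns]
        criterion_sets[crit] = [v for v in cols if v in set(selected)]
    union: list[str] = []
    for crit in rc.CRITERIA:
        for v in criterion_sets[crit]:
            if v not in union:
                union.append(v)
    union = [v for v in cols if v in set(union)]  # stable column order
    log.info(
        "round-1 LASSO %s: min_mse=%d, one_se=%d, noblocking=%d, union=%d",
        response, *(len(criterion_sets[c]) for c in rc.CRITERIA), len(union),
    )
    return RoundOneResult(criterion_sets, union, lambdas)


def run_round1_stepwise(
    designs: list[ImputationDesign],
    response: str,
    round1: RoundOneResult,
    cfg: dict,
) -> tuple[list[sw.FitResult], dict[str, int]]:
    """Stepwise with all pairwise interactions of the round-1 candidates;
    returns per-imputation fits and the cross-imputation term census."""
    scfg = cfg["stepwise"]
    fits = []
    census: dict[str, int] = {}
    if not round1.candidates:
        return fits, census
    # blocking dummies are fixed effects: candidates as mains, never in
    # interactions (an origin-specific slope is not a blocking adjustment)
    blocking = set(designs[0].blocking_columns)
    non_blk = [v for v in round1.candidates if v not in blocking]
    inters = tuple(
        (non_blk[i], non_blk[j])
        for i in range(len(non_blk))
        for j in range(i + 1, len(non_blk))
    )
    pool = sw.TermSet(tuple(round1.candidates), inters)
    for d in designs:
        y = d.responses[response]
        keep = y.notna()
        fit = sw.stepwise_fit(
            d.frame.loc[keep], y[keep].to_numpy(float), pool,
            scfg["penter"], scfg["premove"], scfg["max_steps"],
        )
        fits.append(fit)
        for t in fit.terms:
            census[t] = census.get(t, 0) + 1
    return fits, census


# --------------------------------------------------------------------------
# round 2
# --------------------------------------------------------------------------

@dataclass
class RoundTwoResult:
    surviving: list[str]
    final_mains: list[str]
    final_interactions: list[tuple[str, str]]
    model: PooledModel


def _involves_blocking(term: str, blocking: set[str]) -> bool:
    return any(v in blocking for v in sw.parse_term(term))


def run_round2(
    designs: list[ImputationDesign],
    response: str,
    census: dict[str, int],
    cfg: dict,
) -> RoundTwoResult:
    """Round-2 LASSO (NoBlocking) on the census terms, then the final
    stepwise fit and Rubin's-rule pooling."""
    lcfg, scfg, retain = cfg["lasso"], cfg["stepwise"], cfg["pooling"]["retain"]
    m = len(designs)
    blocking = set(designs[0].blocking_columns)
    terms = sorted(census)
    # design columns: census terms + every blocking dummy (criterion anchor)
    col_terms = list(terms)
    for b in designs[0].blocking_columns:
        if b not in col_terms:
            col_terms.append(b)

    if terms:
        coefs: dict[str, list[float]] = {t: [] for t in terms}
        for d in designs:
            y = d.responses[response]
            keep = y.notna()
            frame = d.frame.loc[keep]
            raw = {}
            for t in col_terms:
                parts = sw.parse_term(t)
                colv = frame[parts[0]].to_numpy(float)
                for pvar in parts[1:]:
                    colv = colv * frame[pvar].to_numpy(float)
                raw[t] = colv
            X = np.column_stack([raw[t] for t in col_terms])
            design = rc.zscore(X, columns=col_terms)
            yc = rc.center(y[keep].to_numpy(float))
            grid = rc.lambda_path(design, yc, lcfg["n_lambda"], lcfg["ratio"])
            path = rc.fit_path(design, yc, grid, lcfg["tol"], lcfg["max_iter"])
            blk = np.array(
                [j for j, name in enumerate(design.columns)
                 if _involves_blocking(name, blocking)],
                int,
            )
            if blk.size:
                sel = rc.select_lambda(path, "noblocking", blocking_columns=blk)
            else:
                sel = rc.select_lambda(path, "min_mse") if path.cv_mse is not None \
                    else rc.LambdaSelection("noblocking", grid[-1],
                                            path.fits[-1].support, path.fits[-1].coef)
            chosen = dict(zip(design.columns, sel.coef))
            for t in terms:
                coefs[t].append(chosen.get(t, 0.0))
        surviving = [t for t in terms
                     if t in set(pooling.select_terms(coefs, retain))
                     and not _involves_blocking(t, blocking)]
    else:
        surviving = []

    final_mains: list[str] = []
    final_inters: list[tuple[str, str]] = []
    for t in surviving:
        parts = sw.parse_term(t)
        if len(parts) == 1:
            if t not in final_mains:
                final_mains.append(t)
        else:
            final_inters.append(tuple(sorted(parts)))  # type: ignore[arg-type]
            for v in parts:
                if v not in final_mains:
                    final_mains.append(v)
    final_mains = [v for v in designs[0].predictor_columns if v in set(final_mains)]

    fits = []
    pool = sw.TermSet(tuple(final_mains), tuple(dict.fromkeys(final_inters)))
    if len(pool) == 0:
        log.info("round-2 surviving set empty for %s; intercept-only model", response)
    for d in designs:
        y = d.responses[response]
        keep = y.notna()
        if len(pool) == 0:
            fits.append(sw.ols_fit(d.frame.loc[keep], y[keep].to_numpy(float), []))
        else:
            fits.append(
                sw.stepwise_fit(
                    d.frame.loc[keep], y[keep].to_numpy(float), pool,
                    scfg["penter"], scfg["premove"], scfg["max_steps"],
                )
            )
    model = pooling.pool_fits(fits, response=response, retain=retain)
    return RoundTwoResult(surviving, final_mains, list(pool.interactions), model)


# --------------------------------------------------------------------------
# report rendering
# --------------------------------------------------------------------------

def sci(x: float) -> str:
    """'1.2 x 10^-3' style scientific notation used in the report tables."""
    if x == 0.0 or not np.isfinite(x):
        return "0.0" if x == 0.0 else "nan"
    exp = int(np.floor(np.log10(abs(x))))
    mant = x / 10.0**exp
    mant = round(mant, 1)
    if abs(mant) >= 10.0:  # rounding pushed the mantissa over a decade
        mant /= 10.0
        exp += 1
    return f"{mant:.1f} x 10^{exp}"


def format_rows(model: PooledModel) -> list[dict[str, str]]:
    rows = []
    for t in model.terms:
        p_cell = f"{t.p_mean:.3f} ± {t.p_sd:.3f}"
        if t.primary:
            p_cell = f"**{p_cell}**"
        if t.secondary:
            p_cell += " †"
        rows.append(
            {
                "term": t.term,
                "estimate": f"{sci(t.estimate)} ± {sci(t.pooled_sd)}",
                "p_value": p_cell,
                "presence": f"{t.presence}/{model.m}",
            }
        )
    return rows


@dataclass
class FinalModelReport:
    models: dict[str, PooledModel]
    round1: dict[str, RoundOneResult]
    round2: dict[str, RoundTwoResult]
    manifest: dict = field(default_factory=dict)


def render_report(
    report: FinalModelReport, out_dir: str, fmt: str = "csv"
) -> dict[str, str]:
    """Write one table per response plus the round-1 selection summary
    and a run manifest; returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for resp in sorted(report.models):
        model = report.models[resp]
        rows = format_rows(model)
        safe = resp.replace("/", "_").replace(":", "_")
        if fmt == "markdown":
            p = os.path.join(out_dir, f"final_{safe}.md")
            lines = [
                f"# Final model: {resp}",
                "",
                f"adjusted R² = {model.adj_r2_mean:.3f} ± {model.adj_r2_sd:.3f} "
                f"(m = {model.m})",
                "",
                "| Term | Estimate ± pooled SD | p-value (mean ± SD) | Presence |",
                "|---|---|---|---|",
            ]
            lines += [
                f"| {r['term']} | {r['estimate']} | {r['p_value']} | {r['presence']} |"
                for r in rows
            ]
            lines += [
                "",
                "Bold: mean p-value below 0.05; †: 80% trimmed mean of "
                "p-value below 0.05. Pooled SD from Rubin's rule.",
                "",
            ]
            with open(p, "w") as fh:
                fh.write("\n".join(lines))
        else:
            p = os.path.join(out_dir, f"final_{safe}.csv")
            df = pd.DataFrame(rows)
            df["adj_r2_mean"] = f"{model.adj_r2_mean:.6g}"
            df["adj_r2_sd"] = f"{model.adj_r2_sd:.6g}"
            df.to_csv(p, index=False)
        paths[resp] = p

    sel_rows = []
    for resp in sorted(report.round1):
        r1 = report.round1[resp]
        for crit, vs in r1.criterion_sets.items():
            sel_rows.append({"response": resp, "criterion": crit,
                             "selected": ";".join(vs)})
        sel_rows.append({"response": resp, "criterion": "union",
                         "selected": ";".join(r1.candidates)})
    p = os.path.join(out_dir, "round1_selection.csv")
    pd.DataFrame(sel_rows).to_csv(p, index=False)
    paths["round1_selection"] = p

    p = os.path.join(out_dir, "models.json")
    with open(p, "w") as fh:
        json.dump(
            {r: pooling.model_to_dict(m) for r, m in sorted(report.models.items())},
            fh, indent=2, sort_keys=True,
        )
    paths["models"] = p

    p = os.path.join(out_dir, "manifest.json")
    with open(p, "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = p
    return paths


# --------------------------------------------------------------------------
# end-to-end
# --------------------------------------------------------------------------

def run_pipeline(
    table: DatasetTable,
    metas: list[VariableMeta],
    bounds: BoundsTable,
    cfg: dict | None = None,
    seed: int = 0,
    out_dir: str | None = None,
    fmt: str = "csv",
) -> FinalModelReport:
    """Full analysis: imputation, two LASSO and two stepwise rounds,
    pooling, and (optionally) report files under ``out_dir``."""
    cfg = cfg if cfg is not None else default_config()
    stack = draw_imputations(table, bounds, cfg["impute"]["m"], seed)
    designs = build_designs(stack, metas)
    responses = [m.name for m in metas if m.role == "response"]

    models: dict[str, PooledModel] = {}
    round1: dict[str, RoundOneResult] = {}
    round2: dict[str, RoundTwoResult] = {}
    for ri, resp in enumerate(responses):
        r1 = run_round1_lasso(designs, resp, cfg, seed, ri)
        round1[resp] = r1
        if r1.skipped:
            continue
        _, census = run_round1_stepwise(designs, resp, r1, cfg)
        r2 = run_round2(designs, resp, census, cfg)
        round2[resp] = r2
        models[resp] = r2.model

    report = FinalModelReport(
        models=models,
        round1=round1,
        round2=round2,
        manifest={
            "seed": seed,
            "m": cfg["impute"]["m"],
            "config_hash": config_hash(cfg),
            "n_obs": table.n_obs,
            "responses": responses,
        },
    )
    if out_dir is not None:
        render_report(report, out_dir, fmt)
    return report
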