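"""One-hot encoding, temporal k-day averages, and response construction.

Derived temporal columns carry the suffixes ``_2DaysAv``, ``_3DaysAv`` and
``_4DaysAv``; the k-day window covers the collection day and the k-1
preceding days, so the window ending at harvest summarizes the recent
growth history alongside the day-of-harvest value itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from milasso.data_model import DatasetTable, VariableMeta

log = logging.getLogger(__name__)

TEMPORAL_SUFFIXES = {2: "_2DaysAv", 3: "_3DaysAv", 4: "_4DaysAv"}


@dataclass
class EncodedDesign:
    """A dataset augmented with dummy and/or k-day-average columns."""

    table: DatasetTable
    metas: list[VariableMeta]
    derived_from: dict[str, str] = field(default_factory=dict)

    @property
    def dummy_columns(self) -> list[str]:
        return [m.name for m in self.metas if m.role == "blocking_dummy"]


def one_hot_encode(
    table: DatasetTable,
    metas: list[VariableMeta],
    variable: str,
    reference_level: str | None = None,
    role: str = "blocking_dummy",
    prefix: str | None = None,
) -> EncodedDesign:
    """Encode a categorical column as c-1 binary dummies.

    The reference level gets all-zero dummies; by default it is the most
    frequent level (ties broken lexicographically). Missing categories
    propagate to missing dummy cells. The original column is retained with
    role ``auxiliary``.
    """
    col = table.values[variable]
    levels = sorted(col.dropna().astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"categorical {variable!r} has {len(levels)} observed level(s); need >= 2")
    if reference_level is None:
        counts = col.astype(str).value_counts()
        top = counts.max()
        reference_level = sorted(c for c in counts.index if counts[c] == top)[0]
    elif str(reference_level) not in levels:
        raise ValueError(f"reference level {reference_level!r} not observed in {variable!r}")
    reference_level = str(reference_level)

    prefix = prefix if prefix is not None else variable
    values = table.values.copy()
    new_metas = [m if m.name != variable else VariableMeta(m.name, "auxiliary", m.kind, m.units, m.temporal)
                 for m in metas]
    derived = {}
    for lev in levels:
        if lev == reference_level:
            continue
        name = f"{prefix}{lev}"
        dummy = (col.astype(str) == lev).astype(float)
        dummy[col.isna()] = np.nan
        values[name] = dummy
        new_metas.append(VariableMeta(name, role, "binary"))
        derived[name] = variable

    out = table.copy()
    out.values = values
    return EncodedDesign(out, new_metas, derived)


def temporal_average(
    series: dict[int, float] | pd.Series, collection_day: int, k: int
) -> float:
    """Arithmetic mean over days ``collection_day-k+1 .. collection_day``.

    Cultures shorter than k days are averaged over the available days
    (flagged in the log) rather than set missing, so no new missingness
    is created. A missing day inside the window makes the average missing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(series, pd.Series):
        series = {int(d): v for d, v in series.items()}
    first = collection_day - k + 1
    if first < 0:
        log.debug("culture shorter than %d days; averaging over days 0..%d", k, collection_day)
        first = 0
    days = range(first, collection_day + 1)
    vals = [series.get(d, np.nan) for d in days]
    return float(np.mean(vals))


def add_temporal_averages(
    table: DatasetTable, metas: list[VariableMeta], ks: tuple[int, ...] = (2, 3, 4)
) -> EncodedDesign:
    """Append ``<var>_kDaysAv`` predictor columns for every temporal variable."""
    values = table.values.copy()
    new_metas = list(metas)
    derived = {}
    temporal_vars = [m.name for m in metas if m.temporal]
    cdays = table.collection_day.astype(int)
    new_cols = {}
    for var in temporal_vars:
        wide = table.series_wide(var)
        arr = wide.to_numpy(float)
        day_pos = {int(d): i for i, d in enumerate(wide.columns)}
        obs_pos = {o: i for i, o in enumerate(wide.index)}
        for k in ks:
            name = f"{var}{TEMPORAL_SUFFIXES[k]}"
            col = np.full(len(values), np.nan)
            for i, obs in enumerate(values.index):
                oi = obs_pos.get(obs)
                if oi is None:
                    continue
                cday = cdays.loc[obs]
                first = max(cday - k + 1, 0)
                pos = [day_pos[d] for d in range(first, cday + 1) if d in day_pos]
                if len(pos) < cday - first + 1:
                    col[i] = np.nan  # a day inside the window has no record
                else:
                    col[i] = arr[oi, pos].mean()
            new_cols[name] = col
            new_metas.append(VariableMeta(name, "predictor", "numeric"))
            derived[name] = var
    if new_cols:
        values = pd.concat(
            [values, pd.DataFrame(new_cols, index=values.index)], axis=1
        )
    out = table.copy()
    out.values = values
    return EncodedDesign(out, new_metas, derived)


def ratio_to_reference(fa_percent: float, c16_percent: float) -> float:
    """Ratio of a fatty acid's percentage to the C16:0 percentage.

    C16:0 is typically the most abundant fatty acid in *Nannochloropsis*,
    which makes it a stable denominator. A non-positive denominator yields
    a missing value with a warning.
    """
    if c16_percent <= 0:
        warnings.warn(
            f"non-positive C16:0 percentage ({c16_percent}); ratio set missing",
            stacklevel=2,
        )
        return float("nan")
    return float(fa_percent) / float(c16_percent)
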