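"""Bounded multiple imputation: m completed copies of a dataset.

Each missing cell (scalar or daily-series) is filled with an independent
uniform draw on its [lower, upper] interval — the maximum-entropy choice
when only limits are known. Observed cells are identical across copies,
and the whole stack is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from milasso.data_model import BoundsTable, DatasetTable

DEFAULT_M = 10


@dataclass
class ImputedStack:
    """m completed datasets plus the provenance needed to reproduce them."""

    m: int
    tables: list[DatasetTable]
    seed: int
    distribution: str = "uniform"

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need m >= 2 imputations")
        if len(self.tables) != self.m:
            raise ValueError("stack length does not match m")

    def __iter__(self):
        return iter(self.tables)

    def __getitem__(self, i: int) -> DatasetTable:
        return self.tables[i]


def draw_imputations(
    table: DatasetTable, bounds: BoundsTable, m: int = DEFAULT_M, seed: int = 0
) -> ImputedStack:
    """Fill every missing cell m times with uniform draws inside its bounds.

    Degenerate intervals (lower == upper) are filled with that value.
    Missing cells without a bound raise; cells of response variables are
    left as-is (responses are handled per-response downstream).
    """
    if m < 2:
        raise ValueError("need m >= 2 imputations")
    rng = np.random.default_rng(seed)

    # stable cell enumeration so the draw order is reproducible
    scalar_cells = []
    for v in table.values.columns:
        col = table.values[v]
        for o in table.values.index[col.isna()]:
            if (o, v) in bounds:
                scalar_cells.append((o, v))
    series_cells = []
    if len(table.series):
        miss = table.series[table.series["value"].isna()]
        for i, row in miss.iterrows():
            key = (row["observation"], row["variable"], int(row["day"]))
            if key in bounds:
                series_cells.append((i, key))

    tables = []
    for _ in range(m):
        t = table.copy()
        for (o, v) in scalar_cells:
            lo, hi = bounds[(o, v)]
            t.values.at[o, v] = lo if lo == hi else rng.uniform(lo, hi)
        for i, key in series_cells:
            lo, hi = bounds[key]
            t.series.at[i, "value"] = lo if lo == hi else rng.uniform(lo, hi)
        tables.append(t)
    return ImputedStack(m=m, tables=tables, seed=seed)
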