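"""Dataset schema, variable roles and delimited-text I/O.

The on-disk layout is four comma-delimited files with single header rows:

``observations.csv``
    ``observation``, ``collection_day``, then one column per scalar
    variable (predictors, responses, dummies, raw categoricals).
``variables.csv``
    ``name``, ``role``, ``kind``, ``units``, ``temporal``.
``series.csv``
    long form ``observation, variable, day, value`` for variables whose
    daily profile is known (day 0 = inoculation).
``bounds.csv``
    ``observation, variable, day, lower, upper`` — one row per missing
    cell; ``day`` empty for scalar cells.

Missing cells are written as empty fields; both empty fields and the
literal ``NA`` are accepted on input.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ROLES = ("predictor", "response", "blocking_dummy", "categorical_raw", "auxiliary")
KINDS = ("numeric", "binary")

_NA_VALUES = ["", "NA"]


class SchemaError(ValueError):
    """Raised when a file violates the dataset schema."""


class ValidationError(ValueError):
    """Raised when a loaded triple violates a dataset invariant."""


@dataclass(frozen=True)
class VariableMeta:
    """Role and type metadata for one variable."""

    name: str
    role: str
    kind: str = "numeric"
    units: str = ""
    temporal: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemaError(
                f"unknown role {self.role!r} for variable {self.name!r}; "
                f"expected one of {ROLES}"
            )
        if self.kind not in KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for variable {self.name!r}")
        if self.role == "blocking_dummy" and self.kind != "binary":
            raise SchemaError(f"blocking dummy {self.name!r} must be binary")


@dataclass
class DatasetTable:
    """Observations x variables with explicit missingness.

    ``values`` is indexed by observation id (NaN marks missing);
    ``series`` holds the daily profiles in long form; ``collection_day``
    gives the biomass-harvest day per observation.
    """

    values: pd.DataFrame
    collection_day: pd.Series
    series: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["observation", "variable", "day", "value"]
        )
    )

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValidationError("dataset needs at least 2 observations")
        if (self.collection_day.dropna() < 0).any():
            raise ValidationError("collection_day must be >= 0")

    @property
    def observations(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_obs(self) -> int:
        return len(self.values)

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def copy(self) -> "DatasetTable":
        return DatasetTable(
            values=self.values.copy(),
            collection_day=self.collection_day.copy(),
            series=self.series.copy(),
        )

    def series_wide(self, variable: str) -> pd.DataFrame:
        """Day-by-observation frame for one temporal variable."""
        sub = self.series[self.series["variable"] == variable]
        return sub.pivot(index="observation", columns="day", values="value")


@dataclass
class BoundsTable:
    """Per-missing-cell [lower, upper] intervals.

    Keys are ``(observation, variable)`` for scalar cells and
    ``(observation, variable, day)`` for daily-series cells.
    """

    entries: dict[tuple, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, (lo, hi) in self.entries.items():
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValidationError(f"non-finite bound for cell {key}")
            if lo > hi:
                raise ValidationError(f"lower > upper for cell {key}: ({lo}, {hi})")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: tuple) -> bool:
        return key in self.entries

    def __getitem__(self, key: tuple) -> tuple[float, float]:
        return self.entries[key]

    def add(self, key: tuple, lower: float, upper: float) -> None:
        if not (np.isfinite(lower) and np.isfinite(upper)):
            raise ValidationError(f"non-finite bound for cell {key}")
        if lower > upper:
            raise ValidationError(f"lower > upper for cell {key}: ({lower}, {upper})")
        self.entries[key] = (float(lower), float(upper))


@dataclass
class ValidationReport:
    missing_counts: dict[str, int]
    zero_variance: list[str]
    role_tallies: dict[str, int]
    issues: list[str]

    @property
    def ok(self) -> bool:
        return not self.issues


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    return str(x).strip().lower() in {"1", "true", "yes"}


def load_variables(meta_path: str | os.PathLike) -> list[VariableMeta]:
    df = pd.read_csv(meta_path, na_values=_NA_VALUES, keep_default_na=False)
    required = {"name", "role"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{meta_path}: needs columns {sorted(required)}")
    metas = []
    for _, row in df.iterrows():
        metas.append(
            VariableMeta(
                name=str(row["name"]),
                role=str(row["role"]),
                kind=str(row.get("kind", "numeric") or "numeric"),
                units=str(row["units"]) if "units" in df.columns and pd.notna(row.get("units")) else "",
                temporal=_parse_bool(row.get("temporal", False)) if "temporal" in df.columns else False,
            )
        )
    names = [m.name for m in metas]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SchemaError(f"duplicate variable names: {dupes}")
    return metas


def load_dataset(
    data_path: str | os.PathLike,
    meta_path: str | os.PathLike,
    bounds_path: str | os.PathLike | None = None,
    series_path: str | os.PathLike | None = None,
) -> tuple[DatasetTable, list[VariableMeta], BoundsTable]:
    """Load and validate the (observations, metadata, bounds[, series]) files.

    Raises :class:`ValidationError` if any missing predictor cell lacks a
    bound entry; bound entries for observed cells are dropped with a warning
    collected on the returned bounds object (attribute ``ignored``).
    """
    metas = load_variables(meta_path)
    obs = pd.read_csv(data_path, na_values=_NA_VALUES, keep_default_na=False)
    if "observation" not in obs.columns:
        raise SchemaError(f"{data_path}: needs an 'observation' column")
    obs = obs.set_index("observation")
    obs.index = obs.index.astype(str)
    if "collection_day" in obs.columns:
        collection_day = obs.pop("collection_day").astype(float)
    else:
        collection_day = pd.Series(0.0, index=obs.index)
    known = {m.name for m in metas}
    unknown = [c for c in obs.columns if c not in known]
    if unknown:
        raise SchemaError(f"columns without metadata: {unknown}")
    roles = {m.name: m.role for m in metas}
    for c in obs.columns:
        if roles[c] in {"categorical_raw", "auxiliary"}:
            try:
                obs[c] = pd.to_numeric(obs[c])
            except (ValueError, TypeError):
                pass  # free-text categorical levels stay as strings
        else:
            obs[c] = pd.to_numeric(obs[c])

    series = pd.DataFrame(columns=["observation", "variable", "day", "value"])
    if series_path is not None and os.path.exists(series_path):
        series = pd.read_csv(series_path, na_values=_NA_VALUES, keep_default_na=False)
        series["observation"] = series["observation"].astype(str)
        series["day"] = series["day"].astype(int)
        series["value"] = pd.to_numeric(series["value"])

    table = DatasetTable(values=obs, collection_day=collection_day, series=series)
    _check_binary_columns(table, metas)

    bounds = BoundsTable()
    ignored: list[tuple] = []
    if bounds_path is not None and os.path.exists(bounds_path):
        bdf = pd.read_csv(bounds_path, na_values=_NA_VALUES, keep_default_na=False)
        for _, row in bdf.iterrows():
            o, v = str(row["observation"]), str(row["variable"])
            day = row.get("day")
            if pd.isna(day):
                key = (o, v)
                observed = v in obs.columns and pd.notna(obs.at[o, v])
            else:
                key = (o, v, int(day))
                hit = series[
                    (series["observation"] == o)
                    & (series["variable"] == v)
                    & (series["day"] == int(day))
                ]
                observed = len(hit) > 0 and hit["value"].notna().all()
            if observed:
                ignored.append(key)  # bound for a non-missing cell: ignored
                continue
            bounds.add(key, float(row["lower"]), float(row["upper"]))
    bounds.ignored = ignored  # type: ignore[attr-defined]

    _check_bounds_cover_missing(table, metas, bounds)
    return table, metas, bounds


def _check_binary_columns(table: DatasetTable, metas: list[VariableMeta]) -> None:
    for m in metas:
        if m.kind == "binary" and m.name in table.values.columns:
            col = table.values[m.name].dropna()
            bad = ~col.isin([0, 1])
            if bad.any():
                raise ValidationError(
                    f"binary column {m.name!r} contains non-{{0,1}} values: "
                    f"{sorted(col[bad].unique().tolist())}"
                )


def _check_bounds_cover_missing(
    table: DatasetTable, metas: list[VariableMeta], bounds: BoundsTable
) -> None:
    roles = {m.name: m.role for m in metas}
    uncovered = []
    for v in table.values.columns:
        if roles.get(v) not in {"predictor", "blocking_dummy"}:
            continue
        for o in table.values.index[table.values[v].isna()]:
            if (o, v) not in bounds:
                uncovered.append((o, v))
    for _, row in table.series[table.series["value"].isna()].iterrows():
        key = (row["observation"], row["variable"], int(row["day"]))
        if roles.get(row["variable"]) == "predictor" and key not in bounds:
            uncovered.append(key)
    if uncovered:
        raise ValidationError(
            f"{len(uncovered)} missing predictor cell(s) without bounds, "
            f"e.g. {uncovered[:5]}"
        )


def save_dataset(
    out_dir: str | os.PathLike,
    table: DatasetTable,
    metas: list[VariableMeta],
    bounds: BoundsTable | None = None,
) -> dict[str, str]:
    """Write the canonical four-file layout; returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    obs = table.values.copy()
    obs.insert(0, "collection_day", table.collection_day)
    obs.index.name = "observation"
    paths["observations"] = p = os.path.join(out_dir, "observations.csv")
    obs.to_csv(p, na_rep="")

    vdf = pd.DataFrame(
        [
            {"name": m.name, "role": m.role, "kind": m.kind, "units": m.units,
             "temporal": m.temporal}
            for m in metas
        ]
    )
    paths["variables"] = p = os.path.join(out_dir, "variables.csv")
    vdf.to_csv(p, index=False)

    paths["series"] = p = os.path.join(out_dir, "series.csv")
    table.series.to_csv(p, index=False, na_rep="")

    if bounds is not None:
        rows = []
        for key, (lo, hi) in sorted(bounds.entries.items(), key=lambda kv: tuple(map(str, kv[0]))):
            day = key[2] if len(key) == 3 else ""
            rows.append(
                {"observation": key[0], "variable": key[1], "day": day,
                 "lower": repr(lo), "upper": repr(hi)}
            )
        bdf = pd.DataFrame(rows, columns=["observation", "variable", "day", "lower", "upper"])
        paths["bounds"] = p = os.path.join(out_dir, "bounds.csv")
        bdf.to_csv(p, index=False)
    return paths


def validate_dataset(table: DatasetTable, metas: list[VariableMeta]) -> ValidationReport:
    """Report-only diagnostics: missing counts, zero-variance, role tallies."""
    missing = {c: int(table.values[c].isna().sum()) for c in table.values.columns}
    roles = {m.name: m.role for m in metas}
    zero_var = []
    issues = []
    for c in table.values.columns:
        if roles.get(c) in {"predictor", "blocking_dummy"}:
            col = table.values[c].dropna()
            if len(col) >= 2 and float(col.std(ddof=1)) == 0.0:
                zero_var.append(c)
                issues.append(f"zero-variance predictor: {c}")
    tallies: dict[str, int] = {}
    for m in metas:
        tallies[m.role] = tallies.get(m.role, 0) + 1
    for c, k in missing.items():
        if k == table.n_obs:
            issues.append(f"all-missing column: {c}")
    return ValidationReport(missing, zero_var, tallies, issues)


def replace_values(table: DatasetTable, values: pd.DataFrame) -> DatasetTable:
    """A copy of ``table`` with a new value matrix (same index/columns order)."""
    return replace(table, values=values)
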