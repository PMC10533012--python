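"""Study-shaped synthetic datasets with known sparse ground truth.

The generator emulates the structure of the real compilation the
pipeline targets: ~40 numeric growth variables (a handful with daily
temporal profiles whose 2/3/4-day averages are strongly collinear with
the day-of-harvest value), categorical data-origin (blocking) and
nitrogen-source variables, bounded missingness, and responses built
from a sparse set of main effects and pairwise interactions plus
per-origin block offsets and Gaussian noise.

Marginals: standard log-normal for concentration-like variables,
uniform on (0, 1) for temperature/pH-like variables; daily series are
AR(1) (rho = 0.8) deviations around a per-observation level, so the
k-day averages correlate strongly with the harvest-day value, as in the
real data.  Missingness is completely at random; every masked cell gets
a bound interval ``true +- bound_halfwidth*|true|`` (with a small
absolute floor) that is guaranteed to contain the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from milasso import features
from milasso.chem_bounds import MediumComposition
from milasso.data_model import BoundsTable, DatasetTable, VariableMeta

BOUND_FLOOR = 0.05  # minimum absolute half-width of a bound interval

DEFAULT_TRUE_TERMS: tuple[tuple[tuple[str, ...], float], ...] = (
    (("x01",), 1.5),
    (("x03",), -1.2),
    (("x07",), 1.0),
    (("x12",), -1.0),
    (("x30",), 2.0),
    (("x01", "x03"), 1.0),
    (("x07", "x30"), -1.2),
)


@dataclass
class SimulationDesign:
    """Knobs of the synthetic study; defaults are the standing study
    conditions used throughout the test suite."""

    n_obs: int = 121
    n_numeric_predictors: int = 40
    n_temporal: int = 6
    n_origin_groups: int = 4
    n_source_levels: int = 3
    true_terms: tuple[tuple[tuple[str, ...], float], ...] = DEFAULT_TRUE_TERMS
    # the NoBlocking criterion presumes origin effects are captured by the
    # measured predictors; the default design satisfies that premise
    # (no residual origin offset). Nonzero offsets are the sensitivity case.
    block_offsets: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    noise_sd: float = 0.25
    missing_prob: float = 0.15
    bound_halfwidth: float = 0.3
    seed: int = 0
    response_name: str = "y"
    ar_rho: float = 0.8
    ar_sd: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_prob < 1.0):
            raise ValueError("missing_prob must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_origin_groups < 2:
            raise ValueError("need at least 2 origin groups")
        if len(self.block_offsets) != self.n_origin_groups:
            raise ValueError("block_offsets must have one entry per origin group")
        names = set(self.predictor_names)
        for term, _ in self.true_terms:
            for v in term:
                if v not in names:
                    raise ValueError(f"true term references unknown predictor {v!r}")

    @property
    def predictor_names(self) -> list[str]:
        return [f"x{i:02d}" for i in range(1, self.n_numeric_predictors + 1)]

    @property
    def temporal_names(self) -> list[str]:
        return self.predictor_names[: self.n_temporal]

    @property
    def true_mains(self) -> list[str]:
        return [t[0] for t, _ in self.true_terms if len(t) == 1]

    @property
    def true_interactions(self) -> list[tuple[str, str]]:
        return [tuple(sorted(t)) for t, _ in self.true_terms if len(t) == 2]


@dataclass
class GroundTruth:
    true_terms: tuple[tuple[tuple[str, ...], float], ...]
    true_values: pd.DataFrame
    true_series: pd.DataFrame
    masked_cells: dict[tuple, float] = field(default_factory=dict)


def _draw_predictors(design: SimulationDesign, rng: np.random.Generator):
    n = design.n_obs
    names = design.predictor_names
    values = pd.DataFrame(index=[f"obs{i:03d}" for i in range(1, n + 1)])
    values.index.name = "observation"
    collection_day = pd.Series(rng.integers(6, 13, size=n).astype(float), index=values.index)

    series_rows = []
    for j, name in enumerate(names):
        if name in design.temporal_names:
            level = rng.uniform(0.0, 1.0, size=n)
            harvest = np.empty(n)
            for i, obs in enumerate(values.index):
                cday = int(collection_day.iloc[i])
                dev = np.empty(cday + 1)
                dev[0] = rng.normal(0.0, design.ar_sd)
                for d in range(1, cday + 1):
                    dev[d] = design.ar_rho * dev[d - 1] + rng.normal(
                        0.0, design.ar_sd * np.sqrt(1.0 - design.ar_rho**2)
                    )
                vals = level[i] + dev
                harvest[i] = vals[-1]
                for d, v in enumerate(vals):
                    series_rows.append((obs, name, d, v))
            values[name] = harvest
        elif j % 2 == 0:
            values[name] = rng.lognormal(0.0, 1.0, size=n)  # concentration-like
        else:
            values[name] = rng.uniform(0.0, 1.0, size=n)  # temperature/pH-like
    series = pd.DataFrame(series_rows, columns=["observation", "variable", "day", "value"])
    return values, series, collection_day


def generate_study(
    design: SimulationDesign,
) -> tuple[DatasetTable, list[VariableMeta], BoundsTable, GroundTruth]:
    """Generate a complete synthetic study: dataset, metadata, bounds
    covering every masked cell, and the ground truth behind them."""
    rng = np.random.default_rng(design.seed)
    values, series, collection_day = _draw_predictors(design, rng)
    n = design.n_obs

    origin = rng.integers(0, design.n_origin_groups, size=n)
    nsource = rng.choice(["NO3", "Urea", "NH4"][: design.n_source_levels],
                         size=n, p=None)
    values["Origin"] = [f"G{g + 1}" for g in origin]
    values["Nsource"] = nsource

    metas = [
        VariableMeta(name, "predictor", "numeric", temporal=name in design.temporal_names)
        for name in design.predictor_names
    ]
    metas += [
        VariableMeta("Origin", "categorical_raw"),
        VariableMeta("Nsource", "categorical_raw"),
    ]

    # response: sparse truth + block offset + noise
    signal = np.zeros(n)
    for term, beta in design.true_terms:
        contrib = np.ones(n)
        for v in term:
            contrib = contrib * values[v].to_numpy(float)
        signal += beta * contrib
    offsets = np.asarray(design.block_offsets, float)[origin]
    y = signal + offsets + rng.normal(0.0, design.noise_sd, size=n)
    values[design.response_name] = y
    metas.append(VariableMeta(design.response_name, "response"))

    table = DatasetTable(values=values, collection_day=collection_day, series=series)

    # one-hot encode origin (blocking dummies) and N source (predictors)
    enc = features.one_hot_encode(table, metas, "Origin", reference_level="G1",
                                  role="blocking_dummy", prefix="Origin")
    enc = features.one_hot_encode(enc.table, enc.metas, "Nsource",
                                  reference_level="NO3", role="predictor",
                                  prefix="Nsource")
    table, metas = enc.table, enc.metas

    truth = GroundTruth(
        true_terms=design.true_terms,
        true_values=table.values.copy(),
        true_series=table.series.copy(),
    )

    # MCAR missingness on numeric predictors; bounds around truth
    bounds = BoundsTable()
    if design.missing_prob > 0:
        for name in design.predictor_names:
            if name in design.temporal_names:
                continue  # handled at the series level below
            mask = rng.random(n) < design.missing_prob
            for obs in table.values.index[mask]:
                true_val = float(table.values.at[obs, name])
                half = max(design.bound_halfwidth * abs(true_val), BOUND_FLOOR)
                lo, hi = true_val - half, true_val + half
                bounds.add((obs, name), lo, hi)
                truth.masked_cells[(obs, name)] = true_val
                table.values.at[obs, name] = np.nan
        srs = table.series
        mask = rng.random(len(srs)) < design.missing_prob
        for i in np.flatnonzero(mask):
            obs, name, day = srs.at[i, "observation"], srs.at[i, "variable"], int(srs.at[i, "day"])
            true_val = float(srs.at[i, "value"])
            half = max(design.bound_halfwidth * abs(true_val), BOUND_FLOOR)
            lo, hi = true_val - half, true_val + half
            bounds.add((obs, name, day), lo, hi)
            truth.masked_cells[(obs, name, day)] = true_val
            srs.at[i, "value"] = np.nan
            if day == int(table.collection_day.loc[obs]):
                # harvest-day value IS the scalar predictor cell
                bounds.add((obs, name), lo, hi)
                truth.masked_cells[(obs, name)] = true_val
                table.values.at[obs, name] = np.nan

    return table, metas, bounds, truth


# --------------------------------------------------------------------------
# chemistry fixture
# --------------------------------------------------------------------------

# reference seawater ion content at S = 35 (mol kg^-1)
_SEAWATER_IONS_S35 = {
    "Na": 0.46906, "Cl": 0.54586, "Mg": 0.05282,
    "Ca": 0.01028, "K": 0.01021, "SO4": 0.02824,
}
_ION_CHARGE = {"Na": 1, "Cl": -1, "Mg": 2, "Ca": 2, "K": 1, "SO4": -2}

F2_NO3 = 8.82e-4   # mol L^-1 NaNO3 in f/2 medium
F2_PO4 = 3.62e-5   # mol L^-1 NaH2PO4 in f/2 medium


def generate_chem_fixture(
    temperature_C: float, salinity_ppt: float, pCO2_atm: float
) -> MediumComposition:
    """An f/2-in-seawater medium composition scaled to the given salinity.

    Sea-salt ions scale linearly with salinity; the f/2 nutrient loads
    (sodium nitrate, sodium phosphate — charge-balanced salts) do not.
    The net strong-ion charge is the summed sea-salt ion charge, the
    quantity the carbonate solver balances against the carbonate species.
    """
    if not (0.0 < temperature_C < 45.0):
        raise ValueError("temperature must be in (0, 45) degC")
    if salinity_ppt < 0 or pCO2_atm < 0:
        raise ValueError("salinity and pCO2 must be >= 0")
    scale = salinity_ppt / 35.0
    ions = {k: v * scale for k, v in _SEAWATER_IONS_S35.items()}
    ions["NO3"] = F2_NO3
    ions["PO4"] = F2_PO4
    net = sum(_ION_CHARGE[k] * c for k, c in ions.items() if k in _ION_CHARGE)
    return MediumComposition(
        salinity_ppt=salinity_ppt, net_strong_charge=net, ions=ions
    )
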