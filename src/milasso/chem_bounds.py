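"""Model-based imputation-bound calculators.

Biomass (ash-free dry weight) bounds from dry weight or cell counts,
nitrate/phosphate bounds from biomass trajectories, a self-contained
seawater carbonate-equilibrium solver for pH and inorganic-carbon
speciation, a residual linear model refining the equilibrium pH, and an
illumination-geometry helper.

The carbonate solver finds the root of the proton condition (charge
balance) with CO2(aq) pinned by Henry's law:

    [H+] + Z = Kw/[H+] + K1*CO2aq/[H+] + 2*K1*K2*CO2aq/[H+]^2

where Z is the net strong-ion charge of the medium (eq L^-1).  The left
minus right side is strictly increasing in [H+], so the root is unique;
it is bracketed on pH in [2, 12] and solved with Brent's method.

Two equilibrium-constant sets are provided and selected by salinity
(configurable):

* ``seawater``: K0 from Weiss (1974), K1/K2 from Lueker et al. (2000)
  (total scale, mol kg-SW^-1), Kw from Millero (DOE 1994).
* ``freshwater``: K1/K2/KH and Kw from Plummer & Busenberg (1982)
  analytic expressions (the set standard geochemical codes ship for
  dilute solutions).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

log = logging.getLogger(__name__)

CELL_WEIGHT_FLOOR_G = 10e-12  # 10 pg, lower-limit single-cell weight


# --------------------------------------------------------------------------
# biomass bounds
# --------------------------------------------------------------------------

def afdw_bounds_from_dw(dw: float) -> tuple[float, float]:
    """AFDW bounds from a dry-weight measurement (g L^-1).

    Ash content is assumed between 1% (upper AFDW limit) and 20%
    (lower limit): lower = 0.80*dw, upper = 0.99*dw.
    """
    if dw <= 0:
        raise ValueError(f"dry weight must be positive, got {dw}")
    return 0.80 * dw, 0.99 * dw


def biomass_bounds_from_cells(
    cell_density_series: np.ndarray, final_biomass: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-day AFDW bounds (g L^-1) from a cell-count time series.

    The upper series assumes the final per-cell weight throughout
    (constant cell weight); the lower series ramps the per-cell weight
    linearly from 10 pg at day 0 to the final per-cell weight at harvest.
    Both endpoints coincide with ``final_biomass`` on the last day.
    """
    counts = np.asarray(cell_density_series, dtype=float)
    if counts.size == 0 or np.any(counts <= 0):
        raise ValueError("cell-density series must be positive")
    if final_biomass <= 0:
        raise ValueError("final biomass must be positive")
    w_final = final_biomass / counts[-1]  # g per cell
    n = counts.size
    if n == 1:
        ramp = np.array([w_final])
    else:
        ramp = np.linspace(CELL_WEIGHT_FLOOR_G, w_final, n)
    lower = counts * ramp
    upper = counts * w_final
    if w_final < CELL_WEIGHT_FLOOR_G:
        warnings.warn(
            "final per-cell weight below 10 pg; biomass bounds swapped",
            stacklevel=2,
        )
        lower, upper = upper, lower
    return lower, upper


# --------------------------------------------------------------------------
# nutrient bounds
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NitrateConsumptionModel:
    """Second-order polynomial for nitrate consumed (mg N L^-1) as a
    function of biomass change dX (g AFDW L^-1) and initial nitrate
    N0 (mg N L^-1):

        consumption = c0 + c_dx*dX + c_dx2*dX^2 + c_n0*N0 + c_n02*N0^2
                      + c_cross*N0*dX

    The default keeps only the linear biomass term at 60 mg N per g of
    biomass formed, a mid-range nitrogen quota for *Nannochloropsis*
    (6% N of AFDW); the remaining coefficients are fit from data where
    consumption series are available.
    """

    c0: float = 0.0
    c_dx: float = 60.0
    c_dx2: float = 0.0
    c_n0: float = 0.0
    c_n02: float = 0.0
    c_cross: float = 0.0

    def consumption(self, initial_no3: float, delta_x: float) -> float:
        dx, n0 = float(delta_x), float(initial_no3)
        c = (self.c0 + self.c_dx * dx + self.c_dx2 * dx * dx
             + self.c_n0 * n0 + self.c_n02 * n0 * n0 + self.c_cross * n0 * dx)
        if c < 0:
            log.info("nitrate model predicted negative consumption (%.3g); clamped to 0", c)
            c = 0.0
        return c


def fit_nitrate_model(
    initial_no3: np.ndarray, delta_x: np.ndarray, consumed: np.ndarray
) -> tuple[NitrateConsumptionModel, float]:
    """Least-squares fit of the full quadratic consumption model; returns
    the model and its R^2."""
    n0 = np.asarray(initial_no3, float)
    dx = np.asarray(delta_x, float)
    y = np.asarray(consumed, float)
    X = np.column_stack([np.ones_like(dx), dx, dx**2, n0, n0**2, n0 * dx])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return NitrateConsumptionModel(*beta), r2


def nitrate_bounds(
    initial_no3: float,
    biomass_change_bounds: tuple[np.ndarray, np.ndarray],
    model: NitrateConsumptionModel | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-day nitrate bounds (mg N L^-1) from biomass-change bounds.

    The lower nitrate bound uses the *upper* biomass trajectory (more
    biomass, more nitrate consumed) and vice versa; both are clamped to
    [0, initial_no3].
    """
    if initial_no3 < 0:
        raise ValueError("initial nitrate must be >= 0")
    model = model or NitrateConsumptionModel()
    dx_lower, dx_upper = (np.atleast_1d(np.asarray(b, float)) for b in biomass_change_bounds)
    lower = np.array([
        np.clip(initial_no3 - model.consumption(initial_no3, d), 0.0, initial_no3)
        for d in dx_upper
    ])
    upper = np.array([
        np.clip(initial_no3 - model.consumption(initial_no3, d), 0.0, initial_no3)
        for d in dx_lower
    ])
    return np.minimum(lower, upper), np.maximum(lower, upper)


P_CONTENT_LOWER = 0.005  # 0.5% of AFDW, minimal phosphorus quota
P_CONTENT_UPPER = 0.025  # 2.5% of AFDW, luxury-uptake quota


def phosphate_bounds(
    initial_p: float, biomass_change_bounds: tuple[float, float]
) -> tuple[float, float]:
    """Phosphate bounds (mg P L^-1) from biomass-change bounds (g L^-1).

    Biomass phosphorus content is assumed between 0.5% (minimal quota)
    and 2.5% (luxury uptake): the lower P bound pairs the 2.5% quota
    with the upper biomass change, the upper bound pairs 0.5% with the
    lower change. Both clamp at zero.
    """
    if initial_p < 0:
        raise ValueError("initial phosphate must be >= 0")
    dx_lower, dx_upper = biomass_change_bounds
    lower = max(0.0, initial_p - P_CONTENT_UPPER * dx_upper * 1000.0)
    upper = max(0.0, initial_p - P_CONTENT_LOWER * dx_lower * 1000.0)
    return min(lower, upper), max(lower, upper)


# --------------------------------------------------------------------------
# carbonate equilibrium
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MediumComposition:
    """Ionic composition of a growth medium (mol L^-1) plus salinity.

    ``net_strong_charge`` is the summed charge of the non-carbonate,
    non-water ions in eq L^-1 — the quantity entering the proton
    condition (positive means excess strong base, i.e. alkalinity).
    """

    salinity_ppt: float
    net_strong_charge: float
    ions: dict[str, float] | None = None


@dataclass(frozen=True)
class CarbonateState:
    """Equilibrium carbonate speciation at a given pCO2."""

    pH: float
    co2aq: float
    hco3: float
    co3: float
    dic: float
    k1: float
    k2: float
    kh: float
    kw: float
    charge_residual: float


def equilibrium_constants(
    temperature_C: float, salinity_ppt: float, constant_set: str = "auto"
) -> tuple[float, float, float, float]:
    """(K1, K2, KH, Kw) at the given temperature and salinity.

    ``constant_set`` is ``seawater``, ``freshwater`` or ``auto``
    (freshwater below 5 ppt).
    """
    T = temperature_C + 273.15
    S = salinity_ppt
    if constant_set == "auto":
        constant_set = "freshwater" if S < 5.0 else "seawater"
    if constant_set == "freshwater":
        # Plummer & Busenberg (1982) analytic expressions, log10 form
        log_kh = 108.3865 + 0.01985076 * T - 6919.53 / T - 40.45154 * np.log10(T) + 669365.0 / T**2
        log_k1 = -356.3094 - 0.06091964 * T + 21834.37 / T + 126.8339 * np.log10(T) - 1684915.0 / T**2
        log_k2 = -107.8871 - 0.03252849 * T + 5151.79 / T + 38.92561 * np.log10(T) - 563713.9 / T**2
        log_kw = -283.9710 - 0.05069842 * T + 13323.00 / T + 102.24447 * np.log10(T) - 1119669.0 / T**2
        return 10.0**log_k1, 10.0**log_k2, 10.0**log_kh, 10.0**log_kw
    if constant_set == "seawater":
        # Weiss (1974) CO2 solubility, mol kg^-1 atm^-1
        ln_kh = (-60.2409 + 93.4517 * (100.0 / T) + 23.3585 * np.log(T / 100.0)
                 + S * (0.023517 - 0.023656 * (T / 100.0) + 0.0047036 * (T / 100.0) ** 2))
        # Lueker et al. (2000), total pH scale
        pk1 = 3633.86 / T - 61.2172 + 9.67770 * np.log(T) - 0.011555 * S + 0.0001152 * S**2
        pk2 = 471.78 / T + 25.9290 - 3.16967 * np.log(T) - 0.01781 * S + 0.0001122 * S**2
        # Millero (DOE 1994) water dissociation in seawater
        ln_kw = (148.9802 - 13847.26 / T - 23.6521 * np.log(T)
                 + (-5.977 + 118.67 / T + 1.0495 * np.log(T)) * np.sqrt(S) - 0.01615 * S)
        return 10.0**-pk1, 10.0**-pk2, np.exp(ln_kh), np.exp(ln_kw)
    raise ValueError(f"unknown constant set {constant_set!r}")


def _proton_condition(h: float, z: float, co2aq: float,
                      k1: float, k2: float, kw: float) -> float:
    # strictly increasing in h -> unique root
    return h + z - kw / h - k1 * co2aq / h - 2.0 * k1 * k2 * co2aq / h**2


def carbonate_equilibrium(
    medium: MediumComposition,
    temperature_C: float,
    pCO2_atm: float,
    constant_set: str = "auto",
    ph_range: tuple[float, float] = (2.0, 12.0),
    xtol: float = 1e-14,
) -> CarbonateState:
    """Equilibrium pH and carbonate speciation of a medium under a CO2
    atmosphere, from a 1-D root-find on the proton condition."""
    if pCO2_atm < 0:
        raise ValueError("pCO2 must be >= 0")
    if not (0.0 < temperature_C < 45.0):
        raise ValueError("temperature must be in (0, 45) degC")
    k1, k2, kh, kw = equilibrium_constants(temperature_C, medium.salinity_ppt, constant_set)
    co2aq = kh * pCO2_atm
    z = medium.net_strong_charge

    def f(ph: float) -> float:
        return _proton_condition(10.0**-ph, z, co2aq, k1, k2, kw)

    lo, hi = ph_range
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"no root in pH [{lo}, {hi}]: f({lo})={flo:.3g}, f({hi})={fhi:.3g}; "
            f"net charge {z:.3g} eq/L, CO2aq {co2aq:.3g} M"
        )
    # f increases with [H+], i.e. decreases with pH
    ph = brentq(lambda p: f(p), lo, hi, xtol=xtol)
    h = 10.0**-ph
    hco3 = k1 * co2aq / h
    co3 = k2 * hco3 / h
    return CarbonateState(
        pH=ph, co2aq=co2aq, hco3=hco3, co3=co3, dic=co2aq + hco3 + co3,
        k1=k1, k2=k2, kh=kh, kw=kw,
        charge_residual=abs(_proton_condition(h, z, co2aq, k1, k2, kw)),
    )


# --------------------------------------------------------------------------
# residual pH model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidualPHModel:
    """Linear model for the proton-activity residual
    r = 10^(-pH_real) - 10^(-pH_equilibrium), with predictors
    dN, dP (mol L^-1 consumed) and aeration rate (vvm)."""

    intercept: float = 0.0
    coef_dN: float = 0.0
    coef_dP: float = 0.0
    coef_vvm: float = 0.0

    def predict(self, dN: float, dP: float, vvm: float) -> float:
        return self.intercept + self.coef_dN * dN + self.coef_dP * dP + self.coef_vvm * vvm


def estimate_ph_with_residual(
    equilibrium_ph: float,
    dN: float,
    dP: float,
    vvm: float,
    model: ResidualPHModel,
    proton_floor: float = 1e-12,
) -> float:
    """Correct an equilibrium pH with the residual model:
    pH = -log10(10^(-pH_eq) + r). Non-positive corrected proton activity
    is clamped at ``proton_floor`` with a warning."""
    if not (0.0 < equilibrium_ph < 14.0):
        raise ValueError("equilibrium pH must be in (0, 14)")
    r = model.predict(dN, dP, vvm)
    if not np.isfinite(r):
        raise ValueError("residual model produced a non-finite residual")
    h = 10.0**-equilibrium_ph + r
    if h <= 0:
        warnings.warn(
            f"corrected proton activity {h:.3g} <= 0; clamped at {proton_floor:g}",
            stacklevel=2,
        )
        h = proton_floor
    return float(-np.log10(h))


def fit_ph_residual_model(
    observations: list[tuple[float, float, float, float, float]],
) -> tuple[ResidualPHModel, float]:
    """Fit the residual model from (real pH, equilibrium pH, dN, dP, vvm)
    tuples; applies only where ambient-air aeration was used. Returns the
    model and its R^2."""
    if len(observations) < 5:
        raise ValueError("need at least 5 observations with known pH")
    arr = np.asarray(observations, float)
    resid = 10.0 ** -arr[:, 0] - 10.0 ** -arr[:, 1]
    X = np.column_stack([np.ones(len(arr)), arr[:, 2], arr[:, 3], arr[:, 4]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design for pH residual model")
    beta, *_ = np.linalg.lstsq(X, resid, rcond=None)
    pred = X @ beta
    ss_tot = float(np.sum((resid - resid.mean()) ** 2))
    ss_res = float(np.sum((resid - pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ResidualPHModel(*beta), r2


# --------------------------------------------------------------------------
# illumination geometry
# --------------------------------------------------------------------------

def light_availability_bounds(
    surface_intensity: float,
    diameter_range_m: tuple[float, float] = (0.05, 0.10),
    working_volume_L: float = 1.0,
) -> tuple[float, float]:
    """Bounds on photon flux per culture volume (umol photons m^-3 s^-1)
    for a cylindrical vessel of unknown diameter lit from one side.

    The illuminated area is approximated by the projected area d*h with
    h = 4V/(pi d^2), so I*A/V = 4I/(pi d): wider vessels receive less
    light per volume, hence the upper bound uses the smallest diameter.
    """
    if surface_intensity < 0 or working_volume_L <= 0:
        raise ValueError("intensity must be >= 0 and volume > 0")
    d_lo, d_hi = diameter_range_m
    if not (0 < d_lo <= d_hi):
        raise ValueError("need 0 < d_lo <= d_hi")
    lower = 4.0 * surface_intensity / (np.pi * d_hi)
    upper = 4.0 * surface_intensity / (np.pi * d_lo)
    return float(lower), float(upper)
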