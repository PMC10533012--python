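import numpy as np
import pytest

from milasso.chem_bounds import (
    MediumComposition,
    NitrateConsumptionModel,
    ResidualPHModel,
    afdw_bounds_from_dw,
    biomass_bounds_from_cells,
    carbonate_equilibrium,
    equilibrium_constants,
    estimate_ph_with_residual,
    fit_nitrate_model,
    fit_ph_residual_model,
    light_availability_bounds,
    nitrate_bounds,
    phosphate_bounds,
)
from milasso.synthetic_data import generate_chem_fixture


class TestBiomassBounds:
    @pytest.mark.parametrize("dw, expected", [(1.0, (0.80, 0.99)), (2.5, (2.00, 2.475))])
    def test_ash_content_limits(self, dw, expected):
        assert afdw_bounds_from_dw(dw) == pytest.approx(expected)

    def test_lower_below_upper_for_any_dw(self):
        for dw in (0.01, 0.5, 7.3):
            lo, hi = afdw_bounds_from_dw(dw)
            assert lo < hi

    def test_nonpositive_dw_rejected(self):
        with pytest.raises(ValueError):
            afdw_bounds_from_dw(0.0)

    def test_cell_count_initial_lower_bound(self):
        # 1e11 cells/L at the 10 pg floor weight -> 1.0 g/L
        counts = np.array([1e11, 2e11, 4e11])
        lo, hi = biomass_bounds_from_cells(counts, final_biomass=8.0)
        assert lo[0] == pytest.approx(1.0)

    def test_final_day_bounds_coincide_with_final_biomass(self):
        counts = np.array([1e11, 2e11, 4e11])
        lo, hi = biomass_bounds_from_cells(counts, final_biomass=8.0)
        assert lo[-1] == pytest.approx(8.0)
        assert hi[-1] == pytest.approx(8.0)

    def test_constant_cell_count_gives_constant_upper(self):
        counts = np.full(4, 2e11)
        _, hi = biomass_bounds_from_cells(counts, final_biomass=3.0)
        assert np.allclose(hi, hi[0])

    def test_tiny_final_weight_swaps_with_warning(self):
        counts = np.array([1e11, 1e12])
        with pytest.warns(UserWarning, match="swapped"):
            lo, hi = biomass_bounds_from_cells(counts, final_biomass=1e-3)
        assert np.all(lo <= hi)


class TestNutrientBounds:
    def test_zero_biomass_change_keeps_initial(self):
        lo, hi = nitrate_bounds(100.0, (np.zeros(3), np.zeros(3)))
        assert np.allclose(lo, 100.0) and np.allclose(hi, 100.0)

    def test_linear_consumption_model(self):
        # 60 mg N per g biomass, upper dX = 0.5 g/L -> lower bound 70 mg
        model = NitrateConsumptionModel(c_dx=60.0)
        lo, hi = nitrate_bounds(100.0, (np.array([0.2]), np.array([0.5])), model)
        assert lo[0] == pytest.approx(70.0)
        assert hi[0] == pytest.approx(88.0)

    def test_consumption_exceeding_initial_clamps_to_zero(self):
        model = NitrateConsumptionModel(c_dx=60.0)
        lo, _ = nitrate_bounds(10.0, (np.array([0.0]), np.array([5.0])), model)
        assert lo[0] == 0.0

    def test_refit_recovers_quadratic_model(self):
        rng = np.random.default_rng(0)
        n0 = rng.uniform(20, 150, 60)
        dx = rng.uniform(0.1, 2.0, 60)
        truth = NitrateConsumptionModel(c0=1.0, c_dx=55.0, c_dx2=-3.0, c_cross=0.05)
        consumed = np.array([truth.consumption(a, b) for a, b in zip(n0, dx)])
        model, r2 = fit_nitrate_model(n0, dx, consumed)
        assert r2 > 0.999
        assert model.c_dx == pytest.approx(55.0, abs=1e-6)

    @pytest.mark.parametrize(
        "initial, dx_lo, dx_hi, expected",
        [
            (20.0, 0.2, 0.4, (10.0, 19.0)),  # 2.5% vs 0.5% P quota
            (20.0, 0.0, 0.0, (20.0, 20.0)),
        ],
    )
    def test_phosphate_quota_bounds(self, initial, dx_lo, dx_hi, expected):
        assert phosphate_bounds(initial, (dx_lo, dx_hi)) == pytest.approx(expected)


def _oracle_ph(medium, temperature_C, pCO2_atm, constant_set="auto"):
    """Independent check: bisection (not Brent) on the proton condition."""
    k1, k2, kh, kw = equilibrium_constants(temperature_C, medium.salinity_ppt, constant_set)
    co2 = kh * pCO2_atm

    def f(ph):
        h = 10.0**-ph
        return h + medium.net_strong_charge - kw / h - k1 * co2 / h - 2 * k1 * k2 * co2 / h**2

    lo, hi = 2.0, 12.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestCarbonateEquilibrium:
    def test_pure_water_neutral_at_25C(self):
        water = MediumComposition(salinity_ppt=0.0, net_strong_charge=0.0)
        state = carbonate_equilibrium(water, 25.0, 0.0)
        assert state.pH == pytest.approx(7.0, abs=0.01)

    def test_pure_water_ambient_co2(self):
        water = MediumComposition(salinity_ppt=0.0, net_strong_charge=0.0)
        state = carbonate_equilibrium(water, 25.0, 10.0**-3.5)
        assert state.pH == pytest.approx(_oracle_ph(water, 25.0, 10.0**-3.5), abs=1e-6)
        assert state.pH == pytest.approx(5.6, abs=0.1)

    def test_ph_monotone_decreasing_in_pco2(self):
        medium = generate_chem_fixture(25.0, 38.0, 4.2e-4)
        phs = [carbonate_equilibrium(medium, 25.0, p).pH
               for p in np.logspace(-5, -1, 20)]
        assert np.all(np.diff(phs) < 0)

    def test_ph_increases_with_strong_base(self):
        base_medium = generate_chem_fixture(25.0, 35.0, 4.2e-4)
        more_base = MediumComposition(
            salinity_ppt=35.0, net_strong_charge=base_medium.net_strong_charge + 1e-3
        )
        assert (carbonate_equilibrium(more_base, 25.0, 4.2e-4).pH
                > carbonate_equilibrium(base_medium, 25.0, 4.2e-4).pH)

    def test_charge_balance_and_dic_conservation(self):
        medium = generate_chem_fixture(20.0, 35.0, 4.2e-4)
        st = carbonate_equilibrium(medium, 20.0, 4.2e-4)
        assert st.charge_residual < 1e-10
        assert st.dic == pytest.approx(st.co2aq + st.hco3 + st.co3)

    def test_agrees_with_bisection_oracle_on_random_media(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            sal = rng.uniform(0.0, 40.0)
            medium = generate_chem_fixture(25.0, sal, 4.2e-4)
            t = rng.uniform(5.0, 40.0)
            p = 10.0 ** rng.uniform(-5.0, -2.0)
            st = carbonate_equilibrium(medium, t, p)
            assert st.pH == pytest.approx(_oracle_ph(medium, t, p), abs=0.05)

    def test_seawater_constants_have_sane_magnitudes(self):
        k1, k2, kh, kw = equilibrium_constants(25.0, 35.0, "seawater")
        assert -np.log10(k1) == pytest.approx(5.85, abs=0.2)   # Lueker pK1*
        assert -np.log10(k2) == pytest.approx(8.97, abs=0.2)   # Lueker pK2*
        assert kh == pytest.approx(0.0284, rel=0.05)           # Weiss K0


class TestResidualPH:
    def test_zero_model_returns_equilibrium(self):
        model = ResidualPHModel()
        assert estimate_ph_with_residual(8.0, 1e-3, 1e-4, 0.5, model) == pytest.approx(8.0)

    def test_positive_residual_shifts_ph_down(self):
        model = ResidualPHModel(intercept=9e-8)
        # 10^-8 + 9e-8 = 1e-7 -> pH 7
        assert estimate_ph_with_residual(8.0, 0, 0, 0, model) == pytest.approx(7.0)

    def test_negative_residual_shifts_ph_up(self):
        model = ResidualPHModel(intercept=-5e-9)
        assert estimate_ph_with_residual(8.0, 0, 0, 0, model) > 8.0

    def test_floor_clamps_nonpositive_activity(self):
        model = ResidualPHModel(intercept=-1e-6)
        with pytest.warns(UserWarning, match="clamped"):
            ph = estimate_ph_with_residual(8.0, 0, 0, 0, model)
        assert ph == pytest.approx(12.0)

    def test_noiseless_fit_recovers_exactly(self):
        rng = np.random.default_rng(3)
        truth = ResidualPHModel(1e-8, 2e-6, -5e-5, 3e-8)
        obs = []
        for _ in range(30):
            dn, dp, vvm = rng.uniform(0, 1e-2), rng.uniform(0, 1e-4), rng.uniform(0, 2)
            ph_eq = rng.uniform(7.0, 8.5)
            r = truth.predict(dn, dp, vvm)
            ph_real = -np.log10(10.0**-ph_eq + r)
            obs.append((ph_real, ph_eq, dn, dp, vvm))
        model, r2 = fit_ph_residual_model(obs)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert model.coef_dN == pytest.approx(truth.coef_dN, rel=1e-6)

    def test_zero_residuals_give_zero_coefficients(self):
        rng = np.random.default_rng(0)
        obs = [(ph, ph, rng.uniform(0, 1e-2), rng.uniform(0, 1e-4), rng.uniform(0, 2))
               for ph in rng.uniform(7.0, 8.5, size=8)]
        model, _ = fit_ph_residual_model(obs)
        assert abs(model.coef_dN) < 1e-12 and abs(model.coef_vvm) < 1e-12

    def test_noisy_fit_recovers_within_3se(self):
        rng = np.random.default_rng(11)
        truth = ResidualPHModel(0.0, 3e-6, 0.0, 5e-8)
        X, resid = [], []
        for _ in range(200):
            dn, dp, vvm = rng.uniform(0, 1e-2), rng.uniform(0, 1e-4), rng.uniform(0, 2)
            X.append((dn, dp, vvm))
            resid.append(truth.predict(dn, dp, vvm) + rng.normal(0, 1e-9))
        obs = []
        for (dn, dp, vvm), r in zip(X, resid):
            ph_eq = 8.0
            obs.append((-np.log10(10.0**-ph_eq + r), ph_eq, dn, dp, vvm))
        model, r2 = fit_ph_residual_model(obs)
        # sigma 1e-9 on n=200: SE(dN) ~ 1e-9/ (sd(dn) sqrt(n)) ~ 2.5e-11
        assert model.coef_dN == pytest.approx(truth.coef_dN, abs=3 * 2.5e-8)
        assert r2 > 0.9


class TestChemFixture:
    def test_zero_salinity_zeroes_sea_ions(self):
        m = generate_chem_fixture(25.0, 0.0, 4.2e-4)
        assert all(m.ions[k] == 0.0 for k in ("Na", "Cl", "Mg", "Ca", "K", "SO4"))
        assert m.ions["NO3"] > 0

    def test_ion_content_scales_linearly_with_salinity(self):
        m38 = generate_chem_fixture(25.0, 38.0, 4.2e-4)
        m19 = generate_chem_fixture(25.0, 19.0, 4.2e-4)
        for k in ("Na", "Cl", "Mg", "Ca", "K", "SO4"):
            assert m38.ions[k] == pytest.approx(2.0 * m19.ions[k])

    def test_fixture_accepted_by_solver(self):
        medium = generate_chem_fixture(25.0, 38.0, 4.2e-4)
        st = carbonate_equilibrium(medium, 25.0, 4.2e-4)
        assert 7.0 < st.pH < 9.5  # alkaline seawater-like medium


class TestIllumination:
    def test_wider_vessel_receives_less_light_per_volume(self):
        lo, hi = light_availability_bounds(100.0, (0.05, 0.10), 1.0)
        assert lo < hi
        assert hi == pytest.approx(4 * 100.0 / (np.pi * 0.05))

    def test_zero_intensity_gives_zero_bounds(self):
        assert light_availability_bounds(0.0) == (0.0, 0.0)
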