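"""Impulse-response model: IRF shape, burden oracle, metrics, albedo."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from grassflux.rf import (
    AlbedoBookkeeping,
    IRFParams,
    albedo_rf,
    burden_from_emissions,
    gwp,
    rf_from_burden,
    run_rf,
)
from grassflux.tables import make_flux_table

P = IRFParams()


def pulse_series(kg, year=1800, span=120):
    years = np.arange(year, year + span)
    values = np.zeros(len(years))
    values[0] = kg
    return pd.Series(values, index=years)


class TestIRFShape:
    def test_pool_fractions_sum_to_one_and_irf_starts_at_one(self):
        assert sum(P.co2_pool_fractions) == pytest.approx(1.0, abs=1e-12)
        for gas in ("co2", "ch4", "n2o"):
            assert P.irf(gas, np.array([0.0]))[0] == pytest.approx(1.0)

    def test_irf_nonnegative_and_nonincreasing(self):
        t = np.linspace(0, 500, 2001)
        for gas in ("co2", "ch4", "n2o"):
            y = P.irf(gas, t)
            assert (y >= 0).all()
            assert (np.diff(y) <= 1e-15).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            replace(P, co2_pool_fractions=(0.5, 0.2, 0.2, 0.2))
        with pytest.raises(ValueError, match="lifetimes"):
            replace(P, ch4_lifetime=-1.0)


class TestBurden:
    def test_zero_emissions_zero_burden(self):
        burden = burden_from_emissions(pulse_series(0.0), "co2", P)
        assert (burden == 0).all()

    def test_start_of_year_reporting_makes_first_year_zero(self):
        burden = burden_from_emissions(pulse_series(1e9), "co2", P)
        assert burden.iloc[0] == 0.0
        assert burden.iloc[1] > 0.0

    def test_co2_pulse_survival_is_irf_normalized(self):
        # one year after a pulse the airborne fraction equals the IRF
        # near t = 0.5-1 yr (emission spread through the pulse year)
        kg = 1e12
        burden = burden_from_emissions(pulse_series(kg), "co2", P)
        frac = burden.iloc[1] * P.kg_per_ppb["co2"] / kg
        assert P.irf("co2", np.array([1.0]))[0] < frac < 1.0

    def test_ch4_decay_matches_closed_form(self):
        # constant-rate oracle: burden(t) = E tau (1 - exp(-t/tau))
        fine = replace(P, steps_per_year=16)
        years = np.arange(1800, 1900)
        rate = 1e9
        burden = burden_from_emissions(pd.Series(rate, index=years), "ch4", fine)
        tau = fine.ch4_lifetime
        for t in (10, 40, 90):
            expected = rate * tau * (1 - np.exp(-t / tau)) / fine.kg_per_ppb["ch4"]
            assert burden.loc[1800 + t] == pytest.approx(expected, rel=0.01)

    def test_ch4_pulse_reaches_1_over_e_at_one_lifetime(self):
        fine = replace(P, steps_per_year=16)
        burden = burden_from_emissions(pulse_series(1e9, span=30), "ch4", fine)
        t0 = 1801  # first reported year after the pulse
        ratio = burden.loc[t0 + round(fine.ch4_lifetime)] / burden.loc[t0]
        assert ratio == pytest.approx(np.exp(-round(fine.ch4_lifetime) / fine.ch4_lifetime), rel=0.05)

    def test_unknown_gas_and_gappy_years_rejected(self):
        with pytest.raises(ValueError, match="gas"):
            burden_from_emissions(pulse_series(1.0), "sf6", P)
        gappy = pd.Series([1.0, 1.0], index=[1800, 1802])
        with pytest.raises(ValueError, match="contiguous"):
            burden_from_emissions(gappy, "co2", P)


class TestRFfromBurden:
    def test_zero_burden_zero_rf(self):
        burden = pd.Series(0.0, index=np.arange(1800, 1810))
        assert (rf_from_burden(burden, "ch4", P).to_numpy() == 0).all()

    def test_n2o_direct_hand_value(self):
        burden = pd.Series(1.0, index=[2000])
        params = replace(P, radiative_efficiency={**P.radiative_efficiency, "n2o": 3e-3})
        out = rf_from_burden(burden, "n2o", params)
        assert out.loc[2000, "rf_n2o_direct"] == pytest.approx(3e-3)  # W m-2 = 3 mW m-2

    def test_indirect_components_proportional_to_direct(self):
        burden = pd.Series(np.linspace(0, 5, 10), index=np.arange(2000, 2010))
        params = replace(P, f_tropO3=0.5, f_stratH2O=0.15)
        out = rf_from_burden(burden, "ch4", params)
        assert np.allclose(out["rf_ch4_tropO3"], 0.5 * out["rf_ch4_direct"])
        assert np.allclose(out["rf_ch4_stratH2O"], 0.15 * out["rf_ch4_direct"])

    def test_log_mode_guards_negative_concentration(self):
        params = replace(P, co2_rf_mode="log")
        burden = pd.Series([-(P.co2_reference_ppm * 1e3) - 1.0], index=[2000])
        with pytest.raises(ValueError, match="negative"):
            rf_from_burden(burden, "co2", params)


class TestGWP:
    def test_co2_is_exactly_one(self):
        assert gwp("co2", 100.0, P) == 1.0
        assert gwp("co2", 20.0, P) == 1.0

    def test_ch4_and_n2o_match_metric_constants(self):
        assert gwp("ch4", 100.0, P, with_feedback=True) == pytest.approx(34.0, rel=0.03)
        assert gwp("n2o", 100.0, P, with_feedback=True) == pytest.approx(267.0, rel=0.03)

    def test_feedback_free_values_sit_in_the_published_family(self):
        # AR5-style parameters without feedback put CH4 near 28, N2O
        # (before the stratospheric-O3 offset) in the 270-300 band
        base = replace(P, gamma_feedback=0.0, f_stratO3=0.0)
        assert 26 < gwp("ch4", 100.0, base, with_feedback=False) < 31
        assert 265 < gwp("n2o", 100.0, base, with_feedback=False) < 305

    def test_shorter_horizon_raises_ch4_metric(self):
        assert gwp("ch4", 20.0, P) > gwp("ch4", 100.0, P)

    def test_invalid_horizon(self):
        with pytest.raises(ValueError, match="horizon"):
            gwp("ch4", 0.0, P)

    def test_step_refinement_converged(self):
        coarse = gwp("ch4", 100.0, replace(P, steps_per_year=4))
        fine = gwp("ch4", 100.0, replace(P, steps_per_year=16))
        assert coarse == pytest.approx(fine, rel=0.01)


def _static_landcover(area_a=1e6, area_b=1e6, years=(1750, 1800, 1850)):
    rows = []
    for y in years:
        rows.append({"region": "A", "year": y, "biome": "forest", "area_km2": area_a})
        rows.append({"region": "A", "year": y, "biome": "grassland_sparse", "area_km2": area_b})
    return pd.DataFrame(rows)


class TestAlbedo:
    def test_constant_landcover_zero_rf(self):
        book = AlbedoBookkeeping({("A", "forest"): 2e-5, ("A", "grassland_sparse"): 0.0})
        out = albedo_rf(_static_landcover(), book)
        assert (out["total"] == 0).all()

    def test_half_factor_hand_value_and_linearity(self):
        lc = _static_landcover()
        # one transition: forest loses 1e6 km2 to sparse grassland by 1850
        lc.loc[(lc["year"] == 1850) & (lc["biome"] == "forest"), "area_km2"] = 0.0
        lc.loc[(lc["year"] == 1850) & (lc["biome"] == "grassland_sparse"), "area_km2"] = 2e6
        book = AlbedoBookkeeping({("A", "forest"): 2e-5, ("A", "grassland_sparse"): 0.0})
        out = albedo_rf(lc, book)
        assert out.loc[1850, "total"] == pytest.approx(0.5 * 2e-5 * -1e6)  # -10 mW m-2
        doubled = AlbedoBookkeeping({k: 2 * v for k, v in book.coefficients.items()})
        assert albedo_rf(lc, doubled).loc[1850, "total"] == pytest.approx(2 * out.loc[1850, "total"])

    def test_missing_coefficient_for_observed_transition(self):
        lc = _static_landcover()
        lc.loc[(lc["year"] == 1850) & (lc["biome"] == "forest"), "area_km2"] = 0.0
        lc.loc[(lc["year"] == 1850) & (lc["biome"] == "grassland_sparse"), "area_km2"] = 2e6
        book = AlbedoBookkeeping({("A", "grassland_sparse"): 0.0})
        with pytest.raises(ValueError, match="forest"):
            albedo_rf(lc, book)


class TestRunRF:
    def _table(self, ch4=0.0, n2o=0.0, co2=0.0, years=range(1900, 1950)):
        rows = []
        for y in years:
            rows += [
                {"region": "A", "year": y, "component": "ch4", "management": "managed", "value": ch4},
                {"region": "A", "year": y, "component": "n2o", "management": "managed", "value": n2o},
                {"region": "A", "year": y, "component": "co2_soil", "management": "sparse", "value": co2},
            ]
        return make_flux_table(rows)

    def test_zero_fluxes_zero_trajectory(self):
        out = run_rf(self._table(), P)
        assert (out.to_numpy() == 0).all()

    def test_first_year_zero_and_total_is_component_sum(self, anthro_fluxes):
        out = run_rf(anthro_fluxes, P)
        assert (out.loc[1750].abs() < 1e-15).all()
        comp_cols = [c for c in out.columns if c != "rf_total"]
        assert np.allclose(out["rf_total"], out[comp_cols].sum(axis=1), rtol=1e-12)

    def test_ch4_only_scenario_isolates_components(self):
        out = run_rf(self._table(ch4=1.0), P)
        assert (out["rf_co2"] == 0).all()
        assert (out["rf_n2o_direct"] == 0).all()
        assert out["rf_ch4_direct"].iloc[-1] > 0

    def test_causality_rf_invariant_to_later_emissions(self):
        base = run_rf(self._table(ch4=1.0), P)
        bumped_table = self._table(ch4=1.0)
        bumped_table.loc[bumped_table["year"] >= 1930, "value"] *= 10
        bumped = run_rf(bumped_table, P)
        pd.testing.assert_series_equal(base.loc[1930], bumped.loc[1930])

    def test_superposition_in_linear_mode(self):
        a = self._table(ch4=1.0, co2=-0.1)
        b = self._table(n2o=0.05, co2=0.2)
        ab = a.copy()
        ab["value"] = a["value"] + b["value"]
        rf_sum = run_rf(a, P)["rf_total"] + run_rf(b, P)["rf_total"]
        rf_joint = run_rf(ab, P)["rf_total"]
        assert np.allclose(rf_joint, rf_sum, rtol=1e-9, atol=1e-15)

    def test_feedback_adds_co2_forcing_to_a_ch4_run(self):
        base = run_rf(self._table(ch4=1.0), P)
        fed = run_rf(self._table(ch4=1.0), P, with_feedback=True)
        assert (base["rf_co2"] == 0).all()
        assert fed["rf_co2"].iloc[-1] > 0
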