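"""Emission factor, LCA GWP accounting, GHGI, and treatment contrasts."""

import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from chamberflux.campaign import (
    CO2,
    CumulativeEmission,
    GASES,
    InputInventory,
    MassBasis,
    Treatment,
    UNDEFINED,
)
from chamberflux.climate import (
    ChamberCO2ExcludedError,
    allocate_inventory_per_harvest,
    contrast,
    emission_factor,
    ghgi,
    gwp_inputs,
    gwp_soil,
    gwp_soil_from_emissions,
    gwp_total,
)
from chamberflux.reference import annual_gwp, gwp_reduction_vs_reference


class TestEmissionFactor:
    def test_no_excess_emission_means_zero(self):
        assert emission_factor(1.5, 1.5, 120.0) == 0.0

    def test_hand_arithmetic(self):
        assert emission_factor(2.69, 0.89, 180.0) == pytest.approx(1.0, rel=1e-12)

    def test_undefined_for_unfertilized(self):
        assert emission_factor(1.0, 0.5, 0.0) is UNDEFINED

    @given(st.floats(0, 10), st.floats(0, 10), st.floats(1, 300))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_fertilized_emission(self, gf_f, gf_n, n_rate):
        e1 = emission_factor(gf_f, gf_n, n_rate)
        e2 = emission_factor(gf_f + 1.0, gf_n, n_rate)
        assert e2 - e1 == pytest.approx(100.0 / n_rate, rel=1e-9)


class TestGwpInputs:
    def test_diesel_only(self):
        inv = InputInventory(n_fertilizer=0, p2o5=0, k2o=0, irrigation=0)
        assert gwp_inputs(inv) == pytest.approx(55.4)

    def test_high_input_inventory_hand_sum(self):
        inv = InputInventory(n_fertilizer=180, p2o5=75, k2o=90, irrigation=300)
        expected = 180 * 8.3 + 75 * 0.79 + 90 * 0.55 + 300 * 2.66 + 55.4
        assert expected == pytest.approx(2456.15)
        assert gwp_inputs(inv) == pytest.approx(2456.15, rel=1e-12)

    def test_doubling_amounts_doubles_gwp_excluding_flat_diesel(self):
        inv1 = InputInventory(n_fertilizer=100, p2o5=50, k2o=40, irrigation=150,
                              diesel_events=False)
        inv2 = InputInventory(n_fertilizer=200, p2o5=100, k2o=80, irrigation=300,
                              diesel_events=False)
        assert gwp_inputs(inv2) == pytest.approx(2 * gwp_inputs(inv1), rel=1e-12)

    def test_missing_factor_is_a_configuration_error(self):
        inv = InputInventory(n_fertilizer=100, emission_factors={"diesel": 55.4})
        with pytest.raises(KeyError, match="n_fertilizer"):
            gwp_inputs(inv)

    def test_monotone_in_nitrogen_amount(self):
        lo = gwp_inputs(InputInventory(n_fertilizer=60, irrigation=300))
        hi = gwp_inputs(InputInventory(n_fertilizer=180, irrigation=300))
        assert hi > lo


class TestGwpSoil:
    def test_zero_fluxes_zero_gwp(self):
        assert gwp_soil(0.0, 0.0) == 0.0

    def test_direct_substitution_with_methane_sink(self):
        assert gwp_soil(1.0, -1.0, MassBasis.GAS, MassBasis.GAS) == pytest.approx(237.0)

    def test_element_to_gas_conversion_factors(self):
        literal = gwp_soil(1.0, -0.3, MassBasis.ELEMENT, MassBasis.ELEMENT)
        converted = gwp_soil(1.0, -0.3, MassBasis.ELEMENT, MassBasis.GAS)
        assert literal == pytest.approx(265 * 1.0 + 28 * -0.3)
        assert converted == pytest.approx(265 * (44 / 28) - 28 * 0.3 * (16 / 12), rel=1e-12)

    def test_chamber_co2_is_rejected_with_the_exclusion_rule(self):
        co2_emission = CumulativeEmission(
            "W2N3", CO2, (dt.date(2024, 3, 13), dt.date(2024, 9, 28)), 5000.0, 30)
        with pytest.raises(ChamberCO2ExcludedError, match="photosynthetic"):
            gwp_soil_from_emissions([co2_emission])

    def test_emission_records_aggregate_by_gas(self):
        mk = lambda gas, gf: CumulativeEmission(
            "T", GASES[gas], (dt.date(2024, 3, 13), dt.date(2024, 9, 28)), gf, 10)
        got = gwp_soil_from_emissions([mk("N2O", 0.8), mk("CH4", -0.5), mk("N2O", 0.2)])
        assert got == pytest.approx(gwp_soil(1.0, -0.5))


class TestGwpTotalAndGhgi:
    def test_total_is_the_sum(self):
        assert gwp_total(0.0, 0.0) == 0.0
        assert gwp_total(1265.39, 2456.15) == pytest.approx(3721.54)

    def test_ghgi_yield_scaling(self):
        assert ghgi(1000.0, 10000.0) == pytest.approx(100.0)
        assert ghgi(3721.54, 17700.0) == pytest.approx(210.3, abs=0.05)

    def test_ghgi_halves_when_yield_doubles(self):
        assert ghgi(1000.0, 20000.0) == pytest.approx(ghgi(1000.0, 10000.0) / 2)

    def test_ghgi_undefined_for_zero_yield(self):
        assert ghgi(1000.0, 0.0) is UNDEFINED

    def test_ghgi_times_yield_recovers_gwp(self):
        gwp = 2823.2
        y = 18907.30
        assert ghgi(gwp, y) * (y / 1000.0) == pytest.approx(gwp, rel=1e-9)


class TestInventoryAllocation:
    def test_per_harvest_shares_sum_to_annual(self):
        tr = Treatment("W2N3", (120, 90, 90), 180.0)
        inv = InputInventory(n_fertilizer=180, irrigation=300)
        parts = allocate_inventory_per_harvest(inv, tr)
        assert sum(gwp_inputs(p) for p in parts) == pytest.approx(gwp_inputs(inv), rel=1e-12)

    def test_nitrogen_follows_basal_topdress_split(self):
        tr = Treatment("W1N2", (40, 30, 30), 120.0)
        parts = allocate_inventory_per_harvest(InputInventory(n_fertilizer=120, irrigation=100), tr)
        assert [p.n_fertilizer for p in parts] == pytest.approx([48.0, 36.0, 36.0])


class TestContrast:
    def test_identity_is_zero(self):
        assert contrast(5.0, 5.0) == 0.0

    def test_reference_table_reduction_matches_headline(self):
        red = contrast(2823.20, 3721.54, "reduction")
        assert round(red, 1) == 24.1

    def test_doubling_is_full_improvement(self):
        assert contrast(10.0, 5.0, "improvement") == pytest.approx(100.0)

    def test_zero_reference_undefined(self):
        with pytest.raises(ZeroDivisionError):
            contrast(1.0, 0.0)


class TestReferenceTables:
    def test_annual_gwp_is_per_harvest_sum(self):
        assert annual_gwp("W2N3") == pytest.approx(1979.94 + 1173.25 + 568.35)
        assert annual_gwp("W2N2") == pytest.approx(2823.20)

    def test_headline_reduction_from_embedded_table(self):
        assert round(gwp_reduction_vs_reference("W2N2"), 1) == 24.1
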