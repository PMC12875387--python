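"""Trapezoidal cumulative emissions, harvest partitioning, event shares."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chamberflux.campaign import GASES, MassBasis, QCFlag
from chamberflux.cumulative import (
    InsufficientCoverageError,
    cumulate,
    event_window_share,
    partition_by_harvest,
)

from conftest import BASE_TIME, make_flux_records


def rectangle_rule_oracle(days, fluxes, gas, basis=MassBasis.GAS, step_min=1.0):
    """Independent fine-grid integral of the piecewise-linear interpolant."""
    span = days[-1] - days[0]
    n_cells = max(int(np.ceil(span * 24 * 60 / step_min)), 1)
    edges = np.linspace(days[0], days[-1], n_cells + 1)
    mids = (edges[:-1] + edges[1:]) / 2
    h = span / n_cells
    integral = np.sum(np.interp(mids, days, fluxes)) * h  # flux·days
    factor = 24.0 * gas.unit_factor_K
    if basis is MassBasis.ELEMENT:
        factor *= gas.element_fraction
    return integral * factor


class TestCumulate:
    def test_constant_flux_closed_form(self):
        recs = make_flux_records([(0, 50.0), (4, 50.0), (10, 50.0)])
        emission = cumulate(recs, basis=MassBasis.GAS)
        assert emission.GF == pytest.approx(50.0 * 10 * 24 * 1e-5, rel=1e-12)

    def test_two_point_trapezoid_hand_arithmetic(self):
        recs = make_flux_records([(0, 100.0), (10, 300.0)])
        gas_mass = cumulate(recs, basis=MassBasis.GAS)
        assert gas_mass.GF == pytest.approx(0.48, rel=1e-12)       # kg N2O/ha
        element = cumulate(recs, basis=MassBasis.ELEMENT)
        assert element.GF == pytest.approx(0.48 * 28 / 44, rel=1e-12)  # kg N/ha
        assert element.unit == "kg N ha-1"

    def test_co2_uses_its_own_unit_factor(self):
        recs = make_flux_records([(0, 100.0), (10, 300.0)], gas_name="CO2")
        emission = cumulate(recs, basis=MassBasis.GAS)
        assert emission.GF == pytest.approx(200 * 240 * 1e-2, rel=1e-12)

    def test_all_negative_ch4_series_is_net_uptake(self):
        recs = make_flux_records([(0, -30.0), (7, -50.0), (14, -20.0)], gas_name="CH4")
        assert cumulate(recs).GF < 0

    def test_single_record_insufficient(self):
        with pytest.raises(InsufficientCoverageError):
            cumulate(make_flux_records([(0, 100.0)]))

    def test_non_pass_records_excluded(self):
        good = make_flux_records([(0, 100.0), (10, 100.0)])
        bad = make_flux_records([(5, 1e6)], qc=QCFlag.NONLINEAR)
        merged = sorted(good + bad, key=lambda r: r.time)
        assert cumulate(merged, basis=MassBasis.GAS).GF == pytest.approx(0.24, rel=1e-12)

    def test_matches_fine_grid_oracle_on_irregular_series(self, rng):
        days = np.sort(rng.uniform(0, 60, 12))
        days[0] = 0.0
        fluxes = rng.uniform(-50, 400, 12)
        recs = make_flux_records(list(zip(days, fluxes)))
        got = cumulate(recs, basis=MassBasis.GAS).GF
        want = rectangle_rule_oracle(days, fluxes, GASES["N2O"])
        assert got == pytest.approx(want, rel=1e-6)

    @given(st.floats(0.1, 10))
    @settings(max_examples=30, deadline=None)
    def test_scaling_fluxes_scales_the_integral(self, c):
        base = [(0, 10.0), (3, 80.0), (9, 40.0), (20, 5.0)]
        scaled = [(d, c * f) for d, f in base]
        gf1 = cumulate(make_flux_records(base), basis=MassBasis.GAS).GF
        gf2 = cumulate(make_flux_records(scaled), basis=MassBasis.GAS).GF
        assert gf2 == pytest.approx(c * gf1, rel=1e-9)


class TestPartitionByHarvest:
    def test_symmetric_split_of_constant_flux(self):
        recs = make_flux_records([(0, 100.0), (10, 100.0), (20, 100.0)])
        h = BASE_TIME + dt.timedelta(days=10)  # boundary exactly mid-span
        parts = partition_by_harvest(recs, [h])
        assert len(parts) == 2
        assert parts[0].GF == pytest.approx(parts[1].GF, rel=1e-9)

    def test_additivity_with_boundary_on_a_record(self):
        recs = make_flux_records([(0, 10.0), (7, 200.0), (14, 50.0), (21, 80.0)])
        total = cumulate(recs).GF
        h = BASE_TIME.date() + dt.timedelta(days=7)
        parts = partition_by_harvest(recs, [h])
        assert sum(p.GF for p in parts) == pytest.approx(total, rel=1e-9)

    def test_additivity_with_interpolated_boundary(self):
        recs = make_flux_records([(0, 10.0), (7, 200.0), (14, 50.0), (21, 80.0)])
        total = cumulate(recs).GF
        harvests = [BASE_TIME.date() + dt.timedelta(days=d) for d in (5, 16)]
        parts = partition_by_harvest(recs, harvests)
        assert len(parts) == 3
        assert sum(p.GF for p in parts) == pytest.approx(total, rel=1e-9)

    def test_harvest_outside_season_rejected(self):
        recs = make_flux_records([(0, 10.0), (10, 10.0)])
        with pytest.raises(ValueError, match="inside the season"):
            partition_by_harvest(recs, [BASE_TIME.date() + dt.timedelta(days=100)])


class TestEventWindowShare:
    def test_window_covering_whole_season_is_one(self):
        recs = make_flux_records([(0, 10.0), (10, 60.0), (20, 10.0)])
        share = event_window_share(recs, [BASE_TIME.date()], window_days=30)
        assert share == pytest.approx(1.0, rel=1e-9)

    def test_no_events_is_zero(self):
        recs = make_flux_records([(0, 10.0), (10, 60.0)])
        assert event_window_share(recs, [], window_days=7) == 0.0

    def test_rectangular_pulse_share_matches_manual_integral(self):
        # flat 10 everywhere, pulse to 110 on days 10..12 (linear edges)
        pairs = [(0, 10.0), (9.99, 10.0), (10, 110.0), (12, 110.0),
                 (12.01, 10.0), (30, 10.0)]
        recs = make_flux_records(pairs)
        event_day = BASE_TIME.date() + dt.timedelta(days=9)
        share = event_window_share(recs, [event_day], window_days=5)
        days = np.array([p[0] for p in pairs])
        fluxes = np.array([p[1] for p in pairs])
        grid = np.linspace(0, 30, 300001)
        vals = np.interp(grid, days, fluxes)
        total = np.trapezoid(vals, grid)
        inside = np.trapezoid(np.where((grid >= 9) & (grid <= 14), vals, 0.0), grid)
        assert share == pytest.approx(inside / total, rel=1e-4)

    def test_overlapping_windows_not_double_counted(self):
        recs = make_flux_records([(0, 10.0), (30, 10.0)])
        d0 = BASE_TIME.date()
        share = event_window_share(recs, [d0, d0 + dt.timedelta(days=2)], window_days=10)
        assert share <= 1.0

    def test_zero_total_emission_is_undefined(self):
        recs = make_flux_records([(0, 0.0), (10, 0.0)])
        with pytest.raises(ZeroDivisionError):
            event_window_share(recs, [BASE_TIME.date()], window_days=7)
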