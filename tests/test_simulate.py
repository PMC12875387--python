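"""Synthetic campaign generator: determinism, driver and flux structure."""

import datetime as dt

import numpy as np
import pytest

from chamberflux.campaign import (
    CH4,
    CO2,
    N2O,
    build_default_design,
)
from chamberflux.flux import estimate_flux
from chamberflux.simulate import (
    NoiseModel,
    SimulationParams,
    chamber_forward_model,
    default_rain_events,
    sampling_schedule,
    simulate_campaign,
    simulate_drivers,
    simulate_fluxes,
)

NOISE_FREE = NoiseModel(flux_lognormal_sd=0.0,
                        concentration_sd={"N2O": 0.0, "CO2": 0.0, "CH4": 0.0},
                        driver_theta_sd=0.0, yield_cv=0.0)


class TestDrivers:
    def test_no_events_means_flat_wfps(self):
        params = SimulationParams(seed=0, rain_events=(), noise=NOISE_FREE)
        design = [t for t in build_default_design() if t.id == "W0N0"]
        drivers = simulate_drivers(params, design, calendar=[])
        drv = drivers["W0N0-r1"]
        t = np.linspace(0, 150, 400)
        assert np.allclose(drv.wfps(t), params.wfps_model.baseline)

    def test_single_irrigation_pulse_height(self):
        params = SimulationParams(seed=0, rain_events=())
        design = [t for t in build_default_design() if t.id == "W2N0"]
        drivers = simulate_drivers(params, design)
        drv = drivers["W2N0-r1"]
        # first irrigation (60 mm on Mar 14) lifts WFPS by pulse_per_mm*60
        before = float(drv.wfps(0.0))
        just_after = float(drv.wfps(1.6))
        rise = params.wfps_model.pulse_per_mm * 60.0
        assert just_after > before
        assert just_after <= before + rise + 1e-9

    def test_w2_wfps_range_wider_than_w0(self):
        params = SimulationParams(seed=0)
        design = [t for t in build_default_design() if t.id in ("W0N0", "W2N0")]
        drivers = simulate_drivers(params, design)
        t = np.linspace(0, 199, 2000)
        rng_w0 = np.ptp(drivers["W0N0-r1"].wfps(t))
        rng_w2 = np.ptp(drivers["W2N0-r1"].wfps(t))
        assert rng_w2 > rng_w0

    def test_available_n_jumps_at_fertilization_and_declines(self):
        params = SimulationParams(seed=0, rain_events=())
        design = [t for t in build_default_design() if t.id == "W0N3"]
        drv = simulate_drivers(params, design)["W0N3-r1"]
        topdress_day = (dt.date(2024, 3, 14) - params.season[0]).days
        before = float(drv.available_n(topdress_day + 0.2))
        after = float(drv.available_n(topdress_day + 0.8))
        assert after > before
        assert float(drv.available_n(60.0)) < after

    def test_deterministic_for_fixed_seed(self):
        a = simulate_drivers(SimulationParams(seed=7))
        b = simulate_drivers(SimulationParams(seed=7))
        oa, ob = a["W1N1-r2"].observations, b["W1N1-r2"].observations
        assert [o.theta_volumetric for o in oa] == [o.theta_volumetric for o in ob]


class TestFluxModels:
    def test_unfertilized_no_event_n2o_stays_at_base(self):
        params = SimulationParams(seed=0, rain_events=())
        design = [t for t in build_default_design() if t.id == "W0N0"]
        drivers = simulate_drivers(params, design, calendar=[])
        models = simulate_fluxes(drivers, params)
        t = np.linspace(0, 199, 500)
        assert np.allclose(models["W0N0-r1"].true_flux(N2O, t), params.n2o.base)

    def test_ch4_always_a_sink(self):
        models = simulate_fluxes(simulate_drivers(SimulationParams(seed=0)),
                                 SimulationParams(seed=0))
        t = np.linspace(0, 199, 500)
        for m in models.values():
            assert np.all(m.true_flux(CH4, t) < 0)

    def test_ch4_uptake_weaker_under_high_irrigation(self):
        params = SimulationParams(seed=0)
        models = simulate_fluxes(simulate_drivers(params), params)
        t = np.linspace(0, 199, 500)
        mean_w0 = np.mean([models[f"W0N{k}-r{r}"].true_flux(CH4, t).mean()
                           for k in range(4) for r in (1, 2, 3)])
        mean_w2 = np.mean([models[f"W2N{k}-r{r}"].true_flux(CH4, t).mean()
                           for k in range(4) for r in (1, 2, 3)])
        assert mean_w2 > mean_w0  # less negative: weaker sink when wetter

    def test_n2o_analytic_integral_matches_quadrature(self):
        params = SimulationParams(seed=0)
        model = simulate_fluxes(simulate_drivers(params), params)["W2N3-r1"]
        closed = model.analytic_cumulative(N2O, 0.0, 150.0)
        grid = np.linspace(0.0, 150.0, 300001)
        quad = np.trapezoid(model.true_flux(N2O, grid), grid) * 24 * 1e-5 * 28 / 44
        # trapezoid is O(h) at the pulse-onset jumps, so the match is
        # looser than machine precision even on a half-minute grid
        assert closed == pytest.approx(quad, rel=1e-4)

    def test_co2_peaks_in_the_warm_window(self):
        params = SimulationParams(seed=0)
        model = simulate_fluxes(simulate_drivers(params), params)["W0N0-r1"]
        t = np.linspace(0, 199, 2000)
        temps = model.drivers.soil_temp(t)
        flux = model.true_flux(CO2, t)
        t_at_max = temps[np.argmax(flux)]
        assert 12.0 <= t_at_max <= 23.0


class TestChamberForwardModel:
    def test_zero_flux_is_flat_at_ambient(self):
        s = chamber_forward_model(0.0, N2O, 20.0, 0.3)
        values = [v for _, v in s.samples]
        assert values == pytest.approx([N2O.ambient_concentration] * 4)

    def test_noise_free_round_trip_all_gases(self):
        for gas, F in ((N2O, 37.5), (CO2, 612.0), (CH4, -48.0)):
            rec = estimate_flux(chamber_forward_model(F, gas, 25.0, 0.3))
            assert rec.flux_F == pytest.approx(F, rel=1e-9)

    def test_noisy_ensemble_mean_unbiased(self):
        rng = np.random.default_rng(42)
        F, n = 80.0, 1000
        recovered = np.empty(n)
        for i in range(n):
            s = chamber_forward_model(F, N2O, 20.0, 0.3, noise_sd=1.0, rng=rng)
            recovered[i] = estimate_flux(s).flux_F
        se = recovered.std(ddof=1) / np.sqrt(n)
        assert abs(recovered.mean() - F) < 2 * se + 1e-9


class TestSamplingSchedule:
    def test_alternate_day_visits_after_events(self):
        params = SimulationParams(seed=0, rain_events=())
        design = build_default_design()
        from chamberflux.campaign import default_calendar
        cal = default_calendar(design)
        tr = next(t for t in design if t.id == "W2N2")
        dates = sampling_schedule(tr, cal, params)
        june_event = dt.date(2024, 6, 4)
        for k in (1, 3, 5, 7, 9):
            assert june_event + dt.timedelta(days=k) in dates
        assert june_event in dates  # morning-of-event visit

    def test_heavy_rain_triggers_next_day_visit(self):
        params = SimulationParams(seed=0)
        design = build_default_design()
        from chamberflux.campaign import default_calendar
        cal = default_calendar(design) + default_rain_events()
        tr = next(t for t in design if t.id == "W0N0")
        dates = sampling_schedule(tr, cal, params)
        heavy = [e for e in default_rain_events() if e.heavy_rain]
        assert heavy  # the default climatology includes >10 mm events
        for e in heavy:
            assert e.date + dt.timedelta(days=1) in dates


class TestFullCampaign:
    def test_bundle_has_36_plots_and_all_gases(self, bundle):
        assert len(bundle.plots) == 36
        assert len(bundle.design) == 12
        assert len(bundle.chamber_series) == 36 * 3
        for tid, per_plot in bundle.yields.items():
            assert len(per_plot) == 3
            assert all(len(v) == 3 for v in per_plot.values())

    def test_bit_identical_under_fixed_seed(self):
        p = SimulationParams(seed=11)
        a, b = simulate_campaign(p), simulate_campaign(p)
        sa = a.chamber_series[("W2N3-r1", "N2O")]
        sb = b.chamber_series[("W2N3-r1", "N2O")]
        assert [s.samples for s in sa] == [s.samples for s in sb]
        assert a.yields == b.yields

    def test_adding_plots_does_not_perturb_existing_streams(self):
        p = SimulationParams(seed=5)
        full = simulate_campaign(p)
        sub = simulate_campaign(p, [t for t in build_default_design() if t.id == "W1N1"])
        assert ([s.samples for s in sub.chamber_series[("W1N1-r1", "N2O")]]
                == [s.samples for s in full.chamber_series[("W1N1-r1", "N2O")]])

    def test_yield_optimum_under_high_water_is_moderate_nitrogen(self, bundle):
        w2 = {t.id: bundle.treatment_yield(t.id) for t in bundle.design
              if t.water_level == "W2"}
        assert max(w2, key=w2.get) == "W2N2"
        assert w2["W2N3"] < w2["W2N2"]

    def test_yield_increases_with_irrigation_at_fixed_nitrogen(self, bundle):
        for n in ("N0", "N1", "N2"):
            ys = [bundle.treatment_yield(f"{w}{n}") for w in ("W0", "W1", "W2")]
            assert ys[0] < ys[1] < ys[2]

    def test_noise_chain_adds_no_bias_to_seasonal_n2o(self):
        """Monte-Carlo over seeds: the estimated seasonal N2O matches the
        noise-free trapezoid at the same sampling dates to <1% on average,
        so measurement noise and QC introduce no systematic bias."""
        from chamberflux.cumulative import cumulate
        from chamberflux.campaign import MassBasis

        design = [t for t in build_default_design() if t.id == "W2N3"]
        rel_errors = []
        for seed in range(25):
            b = simulate_campaign(SimulationParams(seed=seed), design)
            start = b.params.season[0]
            dates = b.sampling_dates["W2N3"]
            tdays = np.array([(d - start).days + 9.5 / 24 for d in dates])
            for plot in ("W2N3-r1", "W2N3-r2", "W2N3-r3"):
                recs = [estimate_flux(s) for s in b.chamber_series[(plot, "N2O")]]
                estimated = cumulate(recs, basis=MassBasis.ELEMENT).GF
                truth = b.flux_models[plot].true_flux(N2O, tdays)
                noise_free = np.trapezoid(truth, tdays) * 24 * 1e-5 * 28 / 44
                rel_errors.append((estimated - noise_free) / noise_free)
        assert abs(np.mean(rel_errors)) < 0.01
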