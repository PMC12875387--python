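"""Synthetic water×nitrogen campaign generator.

Generates complete field campaigns — soil drivers, true gas fluxes,
chamber concentration series, and per-harvest yields — for the
3-irrigation × 4-nitrogen factorial with three replicates, so that every
downstream stage (flux estimation, cumulative integration, resource and
climate metrics) can be exercised and validated without field data.

The flux dynamics are deliberately phenomenological, not process-based:
daily-scale exponential pulses triggered by water and N inputs, a
Gaussian temperature response for soil respiration, and a persistent
methane sink moderated by soil wetness. The generator emulates the
statistical structure the analysis chain assumes —

* N₂O: a low base rate plus event-triggered pulses whose height scales
  with the N dose (or water amount times current mineral N) and with a
  moisture gain peaking at 50–60% WFPS, decaying exponentially over days;
* CO₂: ecosystem respiration peaking at soil temperatures of 15–20 °C,
  modestly amplified by wetter soil;
* CH₄: always-negative uptake whose magnitude shrinks as WFPS rises
  (wet soil suppresses methanotrophy), never crossing into net emission;
* drivers: WFPS jumping at irrigation/rain and decaying exponentially,
  mineral N jumping at fertilization and declining over the season,
  sinusoidal seasonal soil temperature;
* sampling: routine visits every 7–10 days, alternate-day visits for a
  week after each irrigation/fertilization, extra visits after heavy
  (>10 mm) rain;
* noise: mean-one multiplicative lognormal noise on observed fluxes and
  Gaussian measurement noise on chamber concentrations.

Every stochastic stream is seeded from (master seed, plot id, stream),
so adding plots never perturbs existing ones and a fixed seed yields
bit-identical campaigns. The noise-free model is available in closed
form (exactly, for the N₂O pulse integral; by fine-grid quadrature for
the driver-coupled CO₂/CH₄ responses), providing the independent oracle
against which pipeline estimates are checked.
"""

from __future__ import annotations

import datetime as _dt
import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .campaign import (
    CH4,
    CO2,
    GASES,
    HARVEST_DATES,
    N2O,
    SEASON_END,
    SEASON_START,
    ChamberSeries,
    EventKind,
    Gas,
    ManagementEvent,
    MassBasis,
    SoilObservation,
    Treatment,
    build_default_design,
    default_calendar,
)
from .flux import MOLAR_VOLUME_STP

__all__ = [
    "SimulationParams",
    "PlotDrivers",
    "FluxModel",
    "CampaignBundle",
    "default_rain_events",
    "sampling_schedule",
    "simulate_drivers",
    "simulate_fluxes",
    "chamber_forward_model",
    "simulate_campaign",
]


# --- Parameters -------------------------------------------------------------

@dataclass(frozen=True)
class TempModel:
    """Seasonal sinusoid for soil temperature at 0–5 cm."""

    mean: float = 17.0        # °C annual mean of the sinusoid
    amplitude: float = 13.0   # °C; peak near mid-July
    peak_doy: int = 200       # day of year of the maximum
    noise_sd: float = 1.2     # °C daily observation noise


@dataclass(frozen=True)
class WfpsModel:
    """Event-pulsed water-filled pore space."""

    baseline: float = 30.0        # % in the absence of inputs
    pulse_per_mm: float = 0.45    # % WFPS rise per mm of water input
    decay_rate: float = 0.10      # d⁻¹ exponential drying
    bounds: tuple[float, float] = (5.0, 95.0)

    def __post_init__(self) -> None:
        if self.decay_rate <= 0:
            raise ValueError("WFPS decay rate must be positive")
        if not (0 <= self.bounds[0] < self.bounds[1] <= 100):
            raise ValueError("WFPS bounds must satisfy 0 <= lo < hi <= 100")


@dataclass(frozen=True)
class NAvailModel:
    """Fertilization-pulsed plant-available mineral N (NO₃⁻+NH₄⁺)."""

    baseline: float = 22.0        # mg kg⁻¹
    pulse_per_kg_n: float = 1.4   # mg kg⁻¹ rise per kg N ha⁻¹ applied
    decay_rate: float = 0.05      # d⁻¹
    season_decline: float = 0.04  # mg kg⁻¹ d⁻¹ slow background drawdown

    def __post_init__(self) -> None:
        if self.decay_rate <= 0:
            raise ValueError("available-N decay rate must be positive")


@dataclass(frozen=True)
class N2OResponse:
    """Base rate plus event pulses with a 50–60% WFPS moisture gain."""

    base: float = 12.0            # µg m⁻² h⁻¹
    per_kg_n: float = 4.0         # pulse amplitude per kg N ha⁻¹ applied
    per_mm_water: float = 0.012   # water-pulse amplitude per mm per mg kg⁻¹ available N
    pulse_decay: float = 0.10     # d⁻¹; fluxes stay elevated ~1–3 weeks after inputs
    moisture_gain: float = 1.2    # extra gain at the WFPS optimum
    wfps_optimum: float = 55.0    # % centre of the denitrification window
    wfps_width: float = 8.0       # % Gaussian width of the window

    def __post_init__(self) -> None:
        if self.pulse_decay <= 0:
            raise ValueError("N2O pulse decay must be positive")


@dataclass(frozen=True)
class CO2Response:
    """Respiration peaking at 15–20 °C, mildly moisture-amplified."""

    r_max: float = 520.0          # mg m⁻² h⁻¹ at the temperature optimum
    t_opt: float = 17.5           # °C
    t_width: float = 12.0         # °C
    moisture_slope: float = 0.006 # fractional gain per % WFPS above baseline


@dataclass(frozen=True)
class CH4Response:
    """Persistent uptake, suppressed (toward zero) by wet soil."""

    uptake_base: float = 55.0     # µg m⁻² h⁻¹ magnitude at WFPS = 0
    wfps_suppression: float = 0.9 # fraction of uptake lost at WFPS = 100%

    def __post_init__(self) -> None:
        if not 0 <= self.wfps_suppression <= 1:
            raise ValueError("CH4 suppression fraction must lie in [0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    flux_lognormal_sd: float = 0.10      # sd of log flux multiplier (mean-one)
    concentration_sd: dict = field(default_factory=lambda: {
        "N2O": 1.0,   # nL L⁻¹ (ECD repeatability)
        "CO2": 4.0,   # µL L⁻¹ (TCD)
        "CH4": 4.0,   # nL L⁻¹ (FID)
    })
    driver_theta_sd: float = 0.8         # % volumetric moisture
    yield_cv: float = 0.04               # replicate coefficient of variation


@dataclass(frozen=True)
class YieldModel:
    """Concave water×N yield response with the N optimum shifting down
    as irrigation rises (~120 kg N ha⁻¹ under full irrigation)."""

    base_annual: float = 11800.0  # kg ha⁻¹ for the unirrigated, unfertilized plot
    water_gain: float = 0.30      # fractional gain at 300 mm
    n_gain: float = 0.23          # fractional gain at the N optimum
    n_opt_high_water: float = 120.0
    n_opt_shift: float = 60.0     # optimum increase at zero irrigation
    harvest_shares: tuple[float, float, float] = (0.225, 0.465, 0.310)


@dataclass(frozen=True)
class SimulationParams:
    seed: int = 0
    season: tuple[_dt.date, _dt.date] = (SEASON_START, SEASON_END)
    sampling_interval_days: int = 7
    event_sampling_days: int = 9   # alternate-day visits this long after inputs
    temp_model: TempModel = TempModel()
    wfps_model: WfpsModel = WfpsModel()
    navail_model: NAvailModel = NAvailModel()
    n2o: N2OResponse = N2OResponse()
    co2: CO2Response = CO2Response()
    ch4: CH4Response = CH4Response()
    noise: NoiseModel = NoiseModel()
    yield_model: YieldModel = YieldModel()
    chamber_height: float = 0.30
    rain_events: tuple[ManagementEvent, ...] | None = None  # None → default climatology


def default_rain_events() -> list[ManagementEvent]:
    """A fixed semi-arid rain sequence for the 2024 season.

    Concentrated in June–September as at the study region, with several
    heavy (>10 mm) events that trigger extra sampling. Amounts sum to a
    dry-ish growing-season total; all plots receive the same rain.
    """
    raw = [
        ("2024-03-25", 6.0), ("2024-04-08", 12.5), ("2024-04-29", 4.0),
        ("2024-05-20", 9.0), ("2024-06-12", 18.0), ("2024-06-28", 7.5),
        ("2024-07-08", 24.0), ("2024-07-26", 15.0), ("2024-08-05", 5.5),
        ("2024-08-21", 19.5), ("2024-09-06", 11.0), ("2024-09-18", 6.5),
    ]
    return [ManagementEvent(_dt.date.fromisoformat(d), EventKind.RAINFALL, mm)
            for d, mm in raw]


# --- helpers ----------------------------------------------------------------

def _day_of(date: _dt.date, season_start: _dt.date) -> float:
    return float((date - season_start).days)


#: Management inputs are applied at midday, after the 9–11 AM chamber
#: window, so a visit on the event day reads pre-input conditions.
EVENT_TIME_OF_DAY = 0.5

#: Chambers close at 09:30, mid-way through the 9–11 AM sampling window.
SAMPLE_TIME_OF_DAY = 9.5 / 24.0


def _plot_rng(seed: int, plot_id: str, stream: int) -> np.random.Generator:
    # stable per-plot stream: adding plots never perturbs existing draws
    return np.random.default_rng(
        np.random.SeedSequence((int(seed) & 0x7FFFFFFF, zlib.crc32(plot_id.encode()), stream)))


@dataclass
class _Pulse:
    t0: float       # days since season start
    amplitude: float
    decay: float

    def value(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        dt = t - self.t0
        return np.where(dt >= 0, self.amplitude * np.exp(-self.decay * np.maximum(dt, 0.0)), 0.0)

    def integral(self, a: float, b: float) -> float:
        """∫ₐᵇ of the pulse, exact."""
        a = max(a, self.t0)
        if b <= a:
            return 0.0
        lam = self.decay
        return self.amplitude / lam * (math.exp(-lam * (a - self.t0)) - math.exp(-lam * (b - self.t0)))


# --- Drivers ----------------------------------------------------------------

@dataclass
class PlotDrivers:
    """Noise-free driver functions plus daily observations for one plot.

    ``soil_temp``/``wfps``/``available_n`` evaluate the underlying truth
    at fractional days since season start; ``observations`` carry the
    seeded daily measurement-noise realization the pipeline would see.
    """

    plot_id: str
    treatment: Treatment
    season_start: _dt.date
    temp_model: TempModel
    wfps_model: WfpsModel
    navail_model: NAvailModel
    water_pulses: list[_Pulse]
    n_pulses: list[_Pulse]
    observations: list[SoilObservation] = field(default_factory=list)

    def soil_temp(self, t) -> np.ndarray:
        doy0 = self.season_start.timetuple().tm_yday
        doy = doy0 + np.asarray(t, dtype=float)
        m = self.temp_model
        return m.mean + m.amplitude * np.cos(2 * np.pi * (doy - m.peak_doy) / 365.25)

    def wfps(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        w = np.full_like(t, self.wfps_model.baseline)
        for p in self.water_pulses:
            w = w + p.value(t)
        return np.clip(w, *self.wfps_model.bounds)

    def available_n(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        n = (self.navail_model.baseline
             - self.navail_model.season_decline * t) * np.ones_like(t)
        for p in self.n_pulses:
            n = n + p.value(t)
        return np.maximum(n, 1.0)


def _events_for(treatment: Treatment, calendar: Sequence[ManagementEvent],
                season: tuple[_dt.date, _dt.date]) -> list[ManagementEvent]:
    return [e for e in calendar
            if e.applies_to(treatment.id) and season[0] <= e.date <= season[1]]


def simulate_drivers(params: SimulationParams,
                     design: Sequence[Treatment] | None = None,
                     calendar: Sequence[ManagementEvent] | None = None) -> dict[str, PlotDrivers]:
    """Daily soil-driver series for every plot of the design.

    WFPS jumps at each irrigation/rain event by ``pulse_per_mm·amount``
    then dries exponentially; available N jumps at fertilization and
    declines through the season; soil temperature follows the seasonal
    sinusoid. Observations carry seeded daily noise; the returned
    objects also expose the noise-free truth functions. Deterministic
    for a fixed seed.
    """
    design = list(design) if design is not None else build_default_design()
    if calendar is None:
        calendar = default_calendar(design) + list(
            params.rain_events if params.rain_events is not None else default_rain_events())
    start, end = params.season
    n_days = (end - start).days + 1
    days = np.arange(n_days, dtype=float)

    out: dict[str, PlotDrivers] = {}
    for tr in design:
        events = _events_for(tr, calendar, params.season)
        water_pulses = [
            _Pulse(_day_of(e.date, start) + EVENT_TIME_OF_DAY,
                   params.wfps_model.pulse_per_mm * e.amount,
                   params.wfps_model.decay_rate)
            for e in events if e.kind in (EventKind.IRRIGATION, EventKind.RAINFALL) and e.amount > 0
        ]
        n_pulses = [
            _Pulse(_day_of(e.date, start) + EVENT_TIME_OF_DAY,
                   params.navail_model.pulse_per_kg_n * e.amount,
                   params.navail_model.decay_rate)
            for e in events if e.kind is EventKind.FERTILIZATION and e.amount > 0
        ]
        for plot in tr.replicates:
            drv = PlotDrivers(plot, tr, start, params.temp_model,
                              params.wfps_model, params.navail_model,
                              water_pulses, n_pulses)
            rng = _plot_rng(params.seed, plot, 0)
            temp_noise = rng.normal(0, params.temp_model.noise_sd, n_days)
            theta_noise = rng.normal(0, params.noise.driver_theta_sd, n_days)
            porosity = 1.0 - 1.48 / 2.65
            wf = drv.wfps(days)
            temps = drv.soil_temp(days) + temp_noise
            navs = drv.available_n(days)
            for i, d in enumerate(days):
                theta = max(wf[i] * porosity + theta_noise[i], 0.1)
                drv.observations.append(SoilObservation(
                    plot, _dt.datetime.combine(start + _dt.timedelta(days=int(d)),
                                               _dt.time(10, 0)),
                    float(temps[i]), float(theta), 1.48, 2.65, float(navs[i])))
            out[plot] = drv
    return out


# --- Fluxes -----------------------------------------------------------------

@dataclass
class FluxModel:
    """Noise-free flux functions for one plot, with exact integrals.

    ``true_flux(gas, t)`` evaluates the underlying model (per-gas flux
    units, gas-mass basis). ``analytic_cumulative`` integrates it over
    an interval without touching the sampled-trapezoid pipeline: the
    N₂O constant+exponential-pulse model in closed form, the
    driver-coupled CO₂/CH₄ responses by fine-grid quadrature.
    """

    drivers: PlotDrivers
    n2o: N2OResponse
    co2: CO2Response
    ch4: CH4Response
    n2o_pulses: list[_Pulse] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.n2o_pulses:
            self.n2o_pulses = self._build_n2o_pulses()

    def _build_n2o_pulses(self) -> list[_Pulse]:
        pulses = []
        drv = self.drivers
        for p in drv.n_pulses:
            dose = p.amplitude / drv.navail_model.pulse_per_kg_n  # kg N applied
            w = float(drv.wfps(p.t0 + 0.5))
            gain = 1.0 + self.n2o.moisture_gain * math.exp(
                -((w - self.n2o.wfps_optimum) / self.n2o.wfps_width) ** 2)
            pulses.append(_Pulse(p.t0, self.n2o.per_kg_n * dose * gain, self.n2o.pulse_decay))
        for p in drv.water_pulses:
            mm = p.amplitude / drv.wfps_model.pulse_per_mm
            navail = float(drv.available_n(p.t0))
            pulses.append(_Pulse(p.t0, self.n2o.per_mm_water * mm * navail, self.n2o.pulse_decay))
        return pulses

    def true_flux(self, gas: Gas, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if gas.name == "N2O":
            out = np.full_like(t, self.n2o.base)
            for p in self.n2o_pulses:
                out = out + p.value(t)
        elif gas.name == "CO2":
            temp = self.drivers.soil_temp(t)
            wf = self.drivers.wfps(t)
            temp_resp = np.exp(-((temp - self.co2.t_opt) / self.co2.t_width) ** 2)
            moist = 1.0 + self.co2.moisture_slope * (wf - self.drivers.wfps_model.baseline)
            out = self.co2.r_max * temp_resp * np.maximum(moist, 0.1)
        elif gas.name == "CH4":
            wf = self.drivers.wfps(t)
            out = -self.ch4.uptake_base * (1.0 - self.ch4.wfps_suppression * wf / 100.0)
        else:  # pragma: no cover
            raise KeyError(gas.name)
        return out if out.ndim else float(out)

    def analytic_cumulative(self, gas: Gas, t0: float, t1: float,
                            basis: MassBasis = MassBasis.ELEMENT,
                            grid_step: float = 0.02) -> float:
        """Exact/fine-grid integral of the noise-free flux, in kg ha⁻¹."""
        if t1 <= t0:
            raise ValueError("need t1 > t0")
        if gas.name == "N2O":
            integral = self.n2o.base * (t1 - t0) + sum(
                p.integral(t0, t1) for p in self.n2o_pulses)
        else:
            grid = np.linspace(t0, t1, max(int((t1 - t0) / grid_step), 2))
            integral = float(np.trapezoid(self.true_flux(gas, grid), grid))
        factor = 24.0 * gas.unit_factor_K
        if basis is MassBasis.ELEMENT:
            factor *= gas.element_fraction
        return integral * factor


def simulate_fluxes(drivers: dict[str, PlotDrivers],
                    params: SimulationParams) -> dict[str, FluxModel]:
    """Noise-free flux models per plot (noise enters at observation time)."""
    return {plot: FluxModel(drv, params.n2o, params.co2, params.ch4)
            for plot, drv in drivers.items()}


# --- Chamber forward model --------------------------------------------------

def chamber_forward_model(true_flux: float, gas: Gas, Ta: float, H: float,
                          sample_times: Sequence[float] = (0.0, 10.0, 20.0, 30.0),
                          noise_sd: float = 0.0,
                          rng: np.random.Generator | None = None,
                          plot_id: str = "synthetic",
                          deployment_time: _dt.datetime | None = None,
                          ambient: float | None = None) -> ChamberSeries:
    """Concentration series a closed chamber would record for a known flux.

    Exact inverse of the chamber flux formula: the concentration rises
    (or falls, for uptake) linearly from the ambient level with slope
    dC/dt = F / [(M/22.4)·(273/(273+Ta))·60·H], plus optional Gaussian
    measurement noise. With ``noise_sd=0`` the estimation chain recovers
    ``true_flux`` to machine precision.
    """
    slope = true_flux / ((gas.molar_mass_gas / MOLAR_VOLUME_STP)
                         * (273.0 / (273.0 + Ta)) * 60.0 * H)
    base = gas.ambient_concentration if ambient is None else ambient
    times = np.asarray(sample_times, dtype=float)
    conc = base + slope * times
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        conc = conc + rng.normal(0.0, noise_sd, conc.shape)
    when = deployment_time or _dt.datetime(2024, 6, 1, 9, 0)
    return ChamberSeries(plot_id, gas, when, tuple(zip(times, conc)),
                         chamber_height_H=H, chamber_air_temp_Ta=Ta)


# --- Sampling schedule ------------------------------------------------------

def sampling_schedule(treatment: Treatment, calendar: Sequence[ManagementEvent],
                      params: SimulationParams) -> list[_dt.date]:
    """Gas-sampling dates for one treatment.

    Routine visits at the configured 7–10-day interval, alternate-day
    visits starting the day after each irrigation/fertilization for
    ``event_sampling_days``, and next-day visits after heavy (>10 mm)
    rainfall.
    """
    start, end = params.season
    dates = set()
    d = start
    while d <= end:
        dates.add(d)
        d += _dt.timedelta(days=params.sampling_interval_days)
    dates.add(end)  # campaigns close with a final visit on the last day
    for e in _events_for(treatment, calendar, params.season):
        if e.kind in (EventKind.IRRIGATION, EventKind.FERTILIZATION):
            # morning-of-event visit reads pre-input conditions, then
            # alternate-day visits from day 1
            dates.add(e.date)
            for k in range(1, params.event_sampling_days + 1, 2):
                day = e.date + _dt.timedelta(days=k)
                if day <= end:
                    dates.add(day)
        elif e.heavy_rain:
            day = e.date + _dt.timedelta(days=1)
            if day <= end:
                dates.add(day)
    return sorted(dates)


# --- Full campaign ----------------------------------------------------------

@dataclass
class CampaignBundle:
    """Everything one simulated campaign produces."""

    params: SimulationParams
    design: list[Treatment]
    calendar: list[ManagementEvent]
    drivers: dict[str, PlotDrivers]
    flux_models: dict[str, FluxModel]
    chamber_series: dict[tuple[str, str], list[ChamberSeries]]  # (plot, gas) → series
    sampling_dates: dict[str, list[_dt.date]]                   # treatment → dates
    yields: dict[str, dict[str, tuple[float, ...]]]             # treatment → plot → per-harvest kg/ha
    harvest_dates: tuple[_dt.date, ...] = HARVEST_DATES

    @property
    def plots(self) -> list[str]:
        return sorted(self.drivers)

    def treatment_of(self, plot_id: str) -> Treatment:
        return self.drivers[plot_id].treatment

    def treatment_yield(self, treatment_id: str) -> float:
        """Annual yield averaged over replicates, kg ha⁻¹."""
        per_plot = self.yields[treatment_id]
        return float(np.mean([sum(v) for v in per_plot.values()]))


def _simulate_yields(params: SimulationParams, design: Sequence[Treatment]) -> dict:
    ym = params.yield_model
    out: dict[str, dict[str, tuple[float, ...]]] = {}
    for tr in design:
        I = tr.irrigation_total_I
        n_opt = ym.n_opt_high_water + ym.n_opt_shift * (1.0 - I / 300.0)
        x = tr.nitrogen_rate_NF / n_opt
        n_factor = 1.0 + ym.n_gain * x * (2.0 - x)
        annual = ym.base_annual * (1.0 + ym.water_gain * I / 300.0) * n_factor
        per_plot = {}
        for plot in tr.replicates:
            rng = _plot_rng(params.seed, plot, 3)
            noise = rng.normal(1.0, params.noise.yield_cv, len(ym.harvest_shares))
            per_plot[plot] = tuple(float(annual * s * max(z, 0.5))
                                   for s, z in zip(ym.harvest_shares, noise))
        out[tr.id] = per_plot
    return out


def simulate_campaign(params: SimulationParams,
                      design: Sequence[Treatment] | None = None) -> CampaignBundle:
    """One full synthetic campaign: 36 plots, three gases, three harvests.

    Chamber series are generated at each plot's sampling dates by the
    forward chamber model around the noise-free flux, with mean-one
    lognormal flux noise and Gaussian concentration noise. The bundle
    also retains the noise-free flux models as the recovery oracle.
    """
    design = list(design) if design is not None else build_default_design()
    calendar = default_calendar(design) + list(
        params.rain_events if params.rain_events is not None else default_rain_events())
    calendar.sort(key=lambda e: (e.date, e.kind.value, e.treatment_scope))
    drivers = simulate_drivers(params, design, calendar)
    flux_models = simulate_fluxes(drivers, params)

    schedules = {tr.id: sampling_schedule(tr, calendar, params) for tr in design}
    start = params.season[0]
    sigma = params.noise.flux_lognormal_sd
    chamber_series: dict[tuple[str, str], list[ChamberSeries]] = {}
    for tr in design:
        dates = schedules[tr.id]
        tdays = np.array([_day_of(d, start) + SAMPLE_TIME_OF_DAY for d in dates])
        for plot in tr.replicates:
            model = flux_models[plot]
            rng_flux = _plot_rng(params.seed, plot, 1)
            rng_conc = _plot_rng(params.seed, plot, 2)
            temps = model.drivers.soil_temp(tdays) + 4.0  # chamber air runs warm
            for gas in GASES.values():
                series_list = []
                truth = np.atleast_1d(model.true_flux(gas, tdays))
                noise = (np.exp(rng_flux.normal(0.0, sigma, truth.shape) - sigma ** 2 / 2.0)
                         if sigma > 0 else np.ones_like(truth))
                observed = truth * noise
                csd = params.noise.concentration_sd.get(gas.name, 0.0)
                for i, d in enumerate(dates):
                    when = _dt.datetime.combine(d, _dt.time(9, 30))
                    series_list.append(chamber_forward_model(
                        float(observed[i]), gas, float(temps[i]), params.chamber_height,
                        noise_sd=csd, rng=rng_conc, plot_id=plot, deployment_time=when))
                chamber_series[(plot, gas.name)] = series_list

    yields = _simulate_yields(params, design)
    return CampaignBundle(params, design, calendar, drivers, flux_models,
                          chamber_series, schedules, yields)
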