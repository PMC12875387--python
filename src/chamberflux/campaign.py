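"""Domain types and campaign configuration.

Everything downstream — flux estimation, cumulative integration, resource
and climate metrics — shares the vocabulary defined here: gases and their
unit bases, chamber deployments, field treatments, management events, and
the input inventory used for life-cycle accounting.

Unit conventions
----------------
Fluxes are areal rates: µg m⁻² h⁻¹ for N₂O and CH₄, mg m⁻² h⁻¹ for CO₂.
Cumulative emissions are element mass per hectare: kg N ha⁻¹ for N₂O,
kg C ha⁻¹ for CO₂ and CH₄ (a gas-mass basis is available via config).
Water amounts are mm depth; nitrogen rates are kg N ha⁻¹.
"""

from __future__ import annotations

import datetime as _dt
import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "MassBasis",
    "Gas",
    "N2O",
    "CO2",
    "CH4",
    "GASES",
    "StandardGas",
    "STANDARD_GASES",
    "ChamberSeries",
    "QCFlag",
    "FluxRecord",
    "SoilObservation",
    "EventKind",
    "ManagementEvent",
    "Treatment",
    "CumulativeEmission",
    "InputInventory",
    "TreatmentMetrics",
    "QCThresholds",
    "CampaignConfig",
    "UNDEFINED",
    "Undefined",
    "build_default_design",
    "default_calendar",
    "validate_config",
    "HEAVY_RAIN_MM",
]

#: Rainfall above this depth (mm) counts as a heavy event that triggers
#: extra gas sampling.
HEAVY_RAIN_MM = 10.0


class Undefined:
    """Marker for metrics that are undefined for a treatment.

    Ratio metrics (IWP, PFPN, EF, GHGI) have no value when their
    denominator input is zero — e.g. PFPN for an unfertilized plot.
    Reports render this as an en-dash; it is never 0 or infinity, and it
    is falsy so ``value or default`` idioms behave.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED"

    def __bool__(self) -> bool:
        return False


UNDEFINED = Undefined()


class MassBasis(str, enum.Enum):
    """Mass basis for cumulative emissions and warming-potential weighting."""

    GAS = "gas"          # kg of N2O / CO2 / CH4 molecule
    ELEMENT = "element"  # kg of N (N2O) or C (CO2, CH4)


@dataclass(frozen=True)
class Gas:
    """One trace gas with its molar masses and unit bookkeeping.

    ``unit_factor_K`` converts the trapezoid sum (flux unit × hours) to
    kg ha⁻¹ on the gas-mass basis: 1e-5 for the µg-flux gases (N₂O, CH₄)
    and 1e-2 for the mg-flux gas (CO₂).
    """

    name: str
    molar_mass_gas: float      # g mol⁻¹ of the gas molecule
    molar_mass_element: float  # g mol⁻¹ of contained N or C per mole of gas
    flux_unit: str
    slope_unit: str            # dC/dt unit fed to the flux formula
    cumulative_unit: str       # element-basis cumulative unit
    unit_factor_K: float
    ambient_concentration: float  # typical ambient level, in slope-unit concentration

    def __post_init__(self) -> None:
        if self.molar_mass_gas <= 0 or self.molar_mass_element <= 0:
            raise ValueError(f"molar masses must be positive for {self.name}")
        if self.unit_factor_K <= 0:
            raise ValueError(f"unit_factor_K must be positive for {self.name}")

    @property
    def element_fraction(self) -> float:
        """Mass fraction of N or C in the gas molecule (e.g. 28/44 for N₂O)."""
        return self.molar_mass_element / self.molar_mass_gas

    def molar_mass(self, basis: MassBasis = MassBasis.GAS) -> float:
        return self.molar_mass_gas if basis is MassBasis.GAS else self.molar_mass_element

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


# N2O carries two N atoms: element molar mass 28 g N per mol N2O.
N2O = Gas("N2O", 44.0, 28.0, "ug m-2 h-1", "nL L-1 min-1", "kg N ha-1", 1e-5, 330.0)
CO2 = Gas("CO2", 44.0, 12.0, "mg m-2 h-1", "uL L-1 min-1", "kg C ha-1", 1e-2, 420.0)
CH4 = Gas("CH4", 16.0, 12.0, "ug m-2 h-1", "nL L-1 min-1", "kg C ha-1", 1e-5, 1900.0)

GASES: dict[str, Gas] = {g.name: g for g in (N2O, CO2, CH4)}


@dataclass(frozen=True)
class StandardGas:
    """Certified calibration standard used to convert GC peak areas.

    ``certified_concentration_C0`` is in the same concentration unit as
    the gas's chamber series (nL L⁻¹ for N₂O/CH₄, µL L⁻¹ for CO₂).
    """

    gas: Gas
    certified_concentration_C0: float
    peak_area_A0: float = 1.0

    def __post_init__(self) -> None:
        if self.certified_concentration_C0 <= 0:
            raise ValueError("standard concentration C0 must be positive")
        if self.peak_area_A0 <= 0:
            raise ValueError("standard peak area A0 must be positive")


#: Default certified standards. 350 µL m⁻³ ≡ 350 nL L⁻¹ (N₂O);
#: 500 mL m⁻³ ≡ 500 µL L⁻¹ (CO₂); 2 µL m⁻³ ≡ 2 nL L⁻¹ (CH₄).
STANDARD_GASES: dict[str, StandardGas] = {
    "N2O": StandardGas(N2O, 350.0),
    "CO2": StandardGas(CO2, 500.0),
    "CH4": StandardGas(CH4, 2.0),
}


class SeriesMode(str, enum.Enum):
    CONCENTRATION = "concentration"
    PEAK_AREA = "peak_area"


@dataclass(frozen=True)
class ChamberSeries:
    """Timed gas samples from one static-chamber deployment, one gas.

    ``samples`` pairs elapsed minutes since chamber closure with either a
    concentration (slope units) or a raw GC peak area, per ``mode``. The
    standard protocol draws four syringes at 0/10/20/30 min.
    """

    plot_id: str
    gas: Gas
    deployment_time: _dt.datetime
    samples: tuple[tuple[float, float], ...]
    chamber_height_H: float = 0.30   # m
    chamber_air_temp_Ta: float = 20.0  # °C
    mode: SeriesMode = SeriesMode.CONCENTRATION

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple((float(t), float(v)) for t, v in self.samples))
        times = [t for t, _ in self.samples]
        if any(t < 0 for t in times):
            raise ValueError("elapsed minutes must be >= 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("elapsed minutes must be strictly increasing (duplicate timestamps rejected)")
        if self.chamber_height_H <= 0:
            raise ValueError("chamber height must be positive")
        if self.chamber_air_temp_Ta <= -273.0:
            raise ValueError("chamber air temperature below absolute zero")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


class QCFlag(str, enum.Enum):
    PASS = "pass"
    NONLINEAR = "nonlinear"
    INSUFFICIENT = "insufficient"
    REJECTED = "rejected"


@dataclass(frozen=True)
class FluxRecord:
    """One estimated areal flux with its regression diagnostics."""

    plot_id: str
    gas: Gas
    time: _dt.datetime
    flux_F: float          # per-gas flux unit; negative = uptake
    slope_dCdt: float
    r_squared: float
    n_points: int
    qc_flag: QCFlag = QCFlag.PASS

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 or math.isnan(self.r_squared)):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class SoilObservation:
    """Per-plot soil state at one sampling time."""

    plot_id: str
    time: _dt.datetime
    soil_temp: float             # °C at 0–5 cm
    theta_volumetric: float      # volumetric moisture, %
    bulk_density_rho_b: float = 1.48   # g cm⁻³
    particle_density_rho_p: float = 2.65
    available_N: float = 0.0     # NO3⁻ + NH4⁺, mg kg⁻¹

    def __post_init__(self) -> None:
        if self.theta_volumetric < 0:
            raise ValueError("volumetric moisture must be >= 0")
        if not (0 < self.bulk_density_rho_b < self.particle_density_rho_p):
            raise ValueError("require 0 < bulk density < particle density")


class EventKind(str, enum.Enum):
    IRRIGATION = "irrigation"
    FERTILIZATION = "fertilization"
    RAINFALL = "rainfall"
    HARVEST = "harvest"
    SOWING = "sowing"


@dataclass(frozen=True)
class ManagementEvent:
    """One calendar event: water or N input, rainfall, harvest, or sowing.

    ``amount`` is mm for water events and kg N ha⁻¹ for fertilization;
    ``treatment_scope`` is a treatment id, an irrigation level prefix
    (e.g. ``"W2"``), or ``"all"``.
    """

    date: _dt.date
    kind: EventKind
    amount: float = 0.0
    treatment_scope: str = "all"

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("event amounts must be >= 0")

    @property
    def heavy_rain(self) -> bool:
        return self.kind is EventKind.RAINFALL and self.amount > HEAVY_RAIN_MM

    def applies_to(self, treatment_id: str) -> bool:
        scope = self.treatment_scope
        return scope == "all" or treatment_id == scope or treatment_id.startswith(scope)


@dataclass(frozen=True)
class Treatment:
    """One water×nitrogen treatment of the factorial design."""

    id: str
    irrigation_per_harvest: tuple[float, ...]  # mm per harvest cycle
    nitrogen_rate_NF: float                    # kg N ha⁻¹, season total
    replicates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "irrigation_per_harvest", tuple(float(x) for x in self.irrigation_per_harvest))
        if any(x < 0 for x in self.irrigation_per_harvest) or self.nitrogen_rate_NF < 0:
            raise ValueError("irrigation and nitrogen amounts must be >= 0")

    @property
    def irrigation_total_I(self) -> float:
        return float(sum(self.irrigation_per_harvest))

    @property
    def water_level(self) -> str:
        return self.id[:2]

    @property
    def nitrogen_level(self) -> str:
        return self.id[2:]


@dataclass(frozen=True)
class CumulativeEmission:
    """Time-integrated emission of one gas over one interval."""

    subject_id: str              # plot or treatment id
    gas: Gas
    interval: tuple[_dt.date, _dt.date]
    GF: float                    # cumulative emission in ``unit``
    n_measurements: int
    basis: MassBasis = MassBasis.ELEMENT

    def __post_init__(self) -> None:
        if self.interval[1] <= self.interval[0]:
            raise ValueError("interval end must follow start")

    @property
    def unit(self) -> str:
        if self.basis is MassBasis.ELEMENT:
            return self.gas.cumulative_unit
        return f"kg {self.gas.name} ha-1"


#: Input-chain carbon emission factors, kg CO₂-eq per unit of each input.
DEFAULT_EMISSION_FACTORS: dict[str, float] = {
    "n_fertilizer": 8.3,   # per kg N
    "p2o5": 0.79,          # per kg P2O5
    "k2o": 0.55,           # per kg K2O
    "irrigation": 2.66,    # per mm irrigation water (pumping electricity)
    "diesel": 55.4,        # per ha (tillage + harvest passes)
}


@dataclass(frozen=True)
class InputInventory:
    """Seasonal agricultural inputs for one treatment, per hectare."""

    n_fertilizer: float = 0.0   # kg N ha⁻¹
    p2o5: float = 75.0          # kg ha⁻¹
    k2o: float = 90.0           # kg ha⁻¹
    irrigation: float = 0.0     # mm
    diesel_events: bool = True  # flat per-ha tillage+harvest diesel charge
    emission_factors: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EMISSION_FACTORS))

    @property
    def amounts(self) -> dict[str, float]:
        return {
            "n_fertilizer": self.n_fertilizer,
            "p2o5": self.p2o5,
            "k2o": self.k2o,
            "irrigation": self.irrigation,
            "diesel": 1.0 if self.diesel_events else 0.0,
        }


@dataclass
class TreatmentMetrics:
    """Summary metrics for one treatment: yield, efficiency, climate."""

    treatment_id: str
    yield_Y: float                                # kg ha⁻¹, annual
    yield_per_harvest: tuple[float, ...] = ()
    IWP: float | Undefined = UNDEFINED            # kg m⁻³
    PFPN: float | Undefined = UNDEFINED           # kg kg⁻¹
    EF_pct: float | Undefined = UNDEFINED         # % of applied N emitted as N2O-N
    GWP_soil: float = 0.0                         # kg CO2-eq ha⁻¹
    GWP_inputs: float = 0.0
    GWP_total: float = 0.0
    GHGI: float | Undefined = UNDEFINED           # kg CO2-eq t⁻¹


@dataclass(frozen=True)
class QCThresholds:
    """Quality-control rule for chamber regressions.

    A series passes when it has at least ``min_points`` samples and
    either r² ≥ ``r2_min`` or its |slope| is inside the near-zero band
    where r² of a flat series is meaningless.
    """

    r2_min: float = 0.80
    min_points: int = 3
    near_zero_slope: float = 0.1  # slope units; 2× typical measurement SD propagated


# --- Default design and calendar -------------------------------------------

IRRIGATION_SPLITS = {"W0": (0.0, 0.0, 0.0), "W1": (40.0, 30.0, 30.0), "W2": (120.0, 90.0, 90.0)}
NITROGEN_RATES = {"N0": 0.0, "N1": 60.0, "N2": 120.0, "N3": 180.0}

#: Basal : first topdress : second topdress split of the seasonal N rate.
FERTILIZER_SPLIT = (0.40, 0.30, 0.30)


def build_default_design() -> list[Treatment]:
    """The 12-treatment factorial: 3 irrigation levels × 4 N rates.

    W0/W1/W2 apply 0/100/300 mm season totals split 40/30/30% style
    across the three harvest cycles (W1: 40/30/30 mm, W2: 120/90/90 mm);
    N0–N3 apply 0/60/120/180 kg N ha⁻¹. Three replicate plots each.
    """
    design = []
    for w, splits in IRRIGATION_SPLITS.items():
        for n, rate in NITROGEN_RATES.items():
            tid = f"{w}{n}"
            reps = tuple(f"{tid}-r{i}" for i in (1, 2, 3))
            design.append(Treatment(tid, splits, rate, reps))
    return design


# 2023–2024 season calendar: sowing + basal N in autumn, gas sampling from
# green-up (Mar 13) to the last harvest (Sep 28), three harvest cuts.
SEASON_START = _dt.date(2024, 3, 13)
SEASON_END = _dt.date(2024, 9, 28)
HARVEST_DATES = (_dt.date(2024, 5, 15), _dt.date(2024, 7, 20), _dt.date(2024, 9, 27))
IRRIGATION_DATES = (
    (_dt.date(2024, 3, 14), _dt.date(2024, 4, 14)),  # first cycle: total split over two events
    (_dt.date(2024, 6, 4),),
    (_dt.date(2024, 8, 11),),
)
TOPDRESS_DATES = (_dt.date(2024, 3, 14), _dt.date(2024, 6, 4))
SOWING_DATE = _dt.date(2023, 10, 15)


def default_calendar(design: Sequence[Treatment] | None = None) -> list[ManagementEvent]:
    """Management events for the default design over the sampled season.

    Basal N (40%) goes on at sowing, before the sampled season; the two
    30% topdressings and all irrigation events fall inside it. The
    within-season N applied is therefore 60% of each treatment's rate,
    but event amounts record the actual doses for the flux model.
    """
    design = list(design) if design is not None else build_default_design()
    events: list[ManagementEvent] = [ManagementEvent(SOWING_DATE, EventKind.SOWING)]
    for t in design:
        if t.nitrogen_rate_NF > 0:
            events.append(ManagementEvent(SOWING_DATE, EventKind.FERTILIZATION,
                                          FERTILIZER_SPLIT[0] * t.nitrogen_rate_NF, t.id))
            for frac, d in zip(FERTILIZER_SPLIT[1:], TOPDRESS_DATES):
                events.append(ManagementEvent(d, EventKind.FERTILIZATION, frac * t.nitrogen_rate_NF, t.id))
    for w in ("W1", "W2"):
        splits = IRRIGATION_SPLITS[w]
        for cycle_amount, dates in zip(splits, IRRIGATION_DATES):
            per_event = cycle_amount / len(dates)
            for d in dates:
                events.append(ManagementEvent(d, EventKind.IRRIGATION, per_event, w))
    for d in HARVEST_DATES:
        events.append(ManagementEvent(d, EventKind.HARVEST))
    events.sort(key=lambda e: (e.date, e.kind.value, e.treatment_scope))
    return events


@dataclass
class CampaignConfig:
    """Everything a pipeline run needs beyond the raw observations."""

    design: list[Treatment] = field(default_factory=build_default_design)
    calendar: list[ManagementEvent] = field(default_factory=default_calendar)
    inventory_defaults: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EMISSION_FACTORS))
    qc: QCThresholds = field(default_factory=QCThresholds)
    mass_basis: MassBasis = MassBasis.ELEMENT
    season: tuple[_dt.date, _dt.date] = (SEASON_START, SEASON_END)
    reference_treatment: str = "W2N3"
    seed: int = 0

    def inventory_for(self, treatment: Treatment) -> InputInventory:
        return InputInventory(
            n_fertilizer=treatment.nitrogen_rate_NF,
            irrigation=treatment.irrigation_total_I,
            emission_factors=dict(self.inventory_defaults),
        )


def validate_config(config: CampaignConfig) -> list[str]:
    """Check every cross-field invariant; return human-readable violations.

    An empty list means the configuration is internally consistent.
    """
    violations: list[str] = []
    seen = set()
    for t in config.design:
        if t.id in seen:
            violations.append(f"design: duplicate treatment id {t.id}")
        seen.add(t.id)
        if len(t.irrigation_per_harvest) != len(HARVEST_DATES):
            violations.append(
                f"design.{t.id}: irrigation_per_harvest has {len(t.irrigation_per_harvest)} entries, "
                f"expected {len(HARVEST_DATES)}")
    for item, ef in config.inventory_defaults.items():
        if ef < 0:
            violations.append(f"inventory.{item}: emission factor must be >= 0, got {ef}")
    if not (0.0 <= config.qc.r2_min <= 1.0):
        violations.append(f"qc.r2_min: must lie in [0, 1], got {config.qc.r2_min}")
    if config.qc.min_points < 3:
        violations.append(f"qc.min_points: must be >= 3, got {config.qc.min_points}")
    if config.season[1] <= config.season[0]:
        violations.append("season: end must follow start")
    if config.reference_treatment not in seen:
        violations.append(f"reference_treatment: {config.reference_treatment} not in design")
    for ev in config.calendar:
        if ev.amount < 0:
            violations.append(f"calendar.{ev.date}.{ev.kind.value}: amount must be >= 0")
    return violations


def validate_soil_observation(obs_fields: dict) -> list[str]:
    """Field-level checks for soil observations, used by config/IO validation."""
    violations = []
    rho_b = obs_fields.get("bulk_density_rho_b")
    rho_p = obs_fields.get("particle_density_rho_p", 2.65)
    if rho_b is not None and not (0 < rho_b < rho_p):
        violations.append(
            f"bulk_density_rho_b: require 0 < bulk density ({rho_b}) < particle density ({rho_p})")
    theta = obs_fields.get("theta_volumetric")
    if theta is not None and theta < 0:
        violations.append(f"theta_volumetric: must be >= 0, got {theta}")
    return violations
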