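"""Climate-impact metrics: emission factor, LCA GWP, and GHGI.

The N₂O emission factor expresses fertilizer-induced emissions as a
percentage of the applied N, against the unfertilized control *at the
same irrigation level*:

    EF (%) = (GF_F − GF_N) / N_F · 100.

Global warming potential is accounted with a cradle-to-field-gate LCA:

    GWP = GWP_soil + GWP_inputs
    GWP_soil = 265 · GF_N2O + 28 · GF_CH4          (100-yr horizon)
    GWP_inputs = Σ Amount_i · EF_i                 (input-chain CO₂-eq)

Chamber-measured soil CO₂ is deliberately excluded from GWP_soil: a dark
chamber sees ecosystem respiration but not photosynthetic uptake, so
including it would misstate the net carbon balance. Greenhouse-gas
intensity is yield-scaled GWP, GHGI = GWP / Y with Y in t ha⁻¹.
"""

from __future__ import annotations

from typing import Iterable

from .campaign import (
    FERTILIZER_SPLIT,
    CumulativeEmission,
    InputInventory,
    MassBasis,
    Treatment,
    UNDEFINED,
    Undefined,
)

__all__ = [
    "GWP100_N2O",
    "GWP100_CH4",
    "emission_factor",
    "gwp_inputs",
    "gwp_soil",
    "gwp_soil_from_emissions",
    "gwp_total",
    "ghgi",
    "allocate_inventory_per_harvest",
    "contrast",
]

#: 100-year global warming potentials, kg CO2-eq per kg of gas.
GWP100_N2O = 265.0
GWP100_CH4 = 28.0


class ChamberCO2ExcludedError(ValueError):
    """Raised when chamber CO₂ is offered to the soil-GWP accounting."""


def emission_factor(GF_F: float, GF_N: float, N_F: float) -> float | Undefined:
    """Fertilizer-induced N₂O emission factor in %.

    ``GF_F`` and ``GF_N`` are seasonal cumulative N₂O emissions
    (kg N ha⁻¹) of the fertilized treatment and of the unfertilized
    control at the same irrigation level; ``N_F`` is the N rate
    (kg N ha⁻¹). Undefined for unfertilized treatments.
    """
    if N_F < 0:
        raise ValueError("nitrogen rate must be >= 0")
    if N_F == 0:
        return UNDEFINED
    return (GF_F - GF_N) / N_F * 100.0


def gwp_inputs(inventory: InputInventory) -> float:
    """Input-chain GWP, kg CO₂-eq ha⁻¹: Σ Amount_i · EF_i.

    Covers N fertilizer manufacture, P₂O₅ and K₂O, irrigation pumping
    electricity (per mm) and field diesel (flat per ha).
    """
    total = 0.0
    for item, amount in inventory.amounts.items():
        if amount == 0:
            continue
        if item not in inventory.emission_factors:
            raise KeyError(f"no emission factor configured for inventory item {item!r}")
        ef = inventory.emission_factors[item]
        if ef < 0:
            raise ValueError(f"emission factor for {item!r} must be >= 0")
        total += amount * ef
    return total


def _to_basis(value: float, ratio_gas_over_element: float,
              input_basis: MassBasis, weighting_basis: MassBasis) -> float:
    if input_basis is weighting_basis:
        return value
    if input_basis is MassBasis.ELEMENT:   # element → gas
        return value * ratio_gas_over_element
    return value / ratio_gas_over_element  # gas → element


def gwp_soil(GF_N2O: float, GF_CH4: float,
             input_basis: MassBasis = MassBasis.ELEMENT,
             weighting_basis: MassBasis = MassBasis.ELEMENT) -> float:
    """Soil-flux GWP: 265·GF_N2O + 28·GF_CH4, kg CO₂-eq ha⁻¹.

    CH₄ may be negative (soil sink), offsetting part of the N₂O term.
    The default applies the warming potentials to the element-basis
    cumulative emissions as the accounting chain produces them
    (kg N ha⁻¹, kg C ha⁻¹); ``weighting_basis=MassBasis.GAS`` instead
    converts to gas mass first (×44/28 for N₂O, ×16/12 for CH₄). CO₂
    never enters this term.
    """
    n2o = _to_basis(GF_N2O, 44.0 / 28.0, input_basis, weighting_basis)
    ch4 = _to_basis(GF_CH4, 16.0 / 12.0, input_basis, weighting_basis)
    return GWP100_N2O * n2o + GWP100_CH4 * ch4


def gwp_soil_from_emissions(emissions: Iterable[CumulativeEmission],
                            weighting_basis: MassBasis = MassBasis.ELEMENT) -> float:
    """Soil GWP from cumulative-emission records, rejecting chamber CO₂."""
    gf = {"N2O": 0.0, "CH4": 0.0}
    for e in emissions:
        if e.gas.name == "CO2":
            raise ChamberCO2ExcludedError(
                "chamber-measured soil CO2 is excluded from GWP_soil: a dark "
                "chamber captures respiration without photosynthetic uptake, "
                "so only non-CO2 gases (N2O, CH4) enter the soil term")
        gf[e.gas.name] += e.GF if e.basis is MassBasis.ELEMENT else e.GF * e.gas.element_fraction
    return gwp_soil(gf["N2O"], gf["CH4"], MassBasis.ELEMENT, weighting_basis)


def gwp_total(soil: float, inputs: float) -> float:
    """Total LCA GWP: soil term plus input-chain term."""
    return soil + inputs


def ghgi(GWP: float, Y: float) -> float | Undefined:
    """Greenhouse-gas intensity, kg CO₂-eq per tonne of dry yield."""
    if Y < 0:
        raise ValueError("yield must be >= 0")
    if Y == 0:
        return UNDEFINED
    return GWP / (Y / 1000.0)


def allocate_inventory_per_harvest(inventory: InputInventory,
                                   treatment: Treatment) -> list[InputInventory]:
    """Split the seasonal inventory into per-harvest-cycle shares.

    N fertilizer follows the basal/topdressing split (40/30/30%),
    irrigation follows the treatment's per-cycle depths, and the
    season-wide items (P₂O₅, K₂O, diesel) are spread evenly. The shares
    sum to the seasonal inventory, so annual GWP is allocation-invariant.
    """
    n_cycles = len(treatment.irrigation_per_harvest)
    total_irr = treatment.irrigation_total_I
    out = []
    for i in range(n_cycles):
        irr_share = (treatment.irrigation_per_harvest[i] / total_irr) if total_irr > 0 else 0.0
        factors = dict(inventory.emission_factors)
        if inventory.diesel_events:
            # flat per-ha charge: split evenly by scaling the per-cycle factor
            factors["diesel"] = factors.get("diesel", 0.0) / n_cycles
        out.append(InputInventory(
            n_fertilizer=inventory.n_fertilizer * FERTILIZER_SPLIT[i],
            p2o5=inventory.p2o5 / n_cycles,
            k2o=inventory.k2o / n_cycles,
            irrigation=inventory.irrigation * irr_share,
            diesel_events=inventory.diesel_events,
            emission_factors=factors,
        ))
    return out


def contrast(value: float, reference: float, kind: str = "reduction") -> float:
    """Relative change of ``value`` against a reference treatment, in %.

    ``kind="reduction"`` reports (ref − value)/ref·100 (positive when the
    candidate emits less); ``kind="improvement"`` reports
    (value − ref)/ref·100 (positive when the candidate yields more).
    """
    if reference == 0:
        raise ZeroDivisionError("contrast undefined for a zero reference value")
    if kind == "reduction":
        return (reference - value) / reference * 100.0
    if kind == "improvement":
        return (value - reference) / reference * 100.0
    raise ValueError(f"unknown contrast kind {kind!r}")
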