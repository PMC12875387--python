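"""Soil water status and resource-efficiency metrics.

Water-filled pore space relates volumetric moisture to total porosity:

    WFPS (%) = θv / (1 − ρb/ρp)

with θv the volumetric moisture content in %, ρb the bulk density and ρp
the particle density (2.65 g cm⁻³ for mineral soils unless measured).

Irrigation water productivity IWP = Y / I (kg dry hay per m³ irrigation;
1 mm depth = 10 m³ ha⁻¹) and partial factor productivity of nitrogen
PFPN = Y / N (kg hay per kg fertilizer N) summarize how efficiently each
input converts to yield. Both are undefined — not zero — for treatments
that received none of the input; callers get the UNDEFINED marker, which
reports render as "–".
"""

from __future__ import annotations

import numpy as np

from .campaign import UNDEFINED, Undefined

__all__ = ["wfps", "gravimetric_to_volumetric", "iwp", "pfpn", "annual_yield"]


class PorosityError(ValueError):
    pass


def wfps(theta: float, rho_b: float, rho_p: float = 2.65) -> float:
    """Water-filled pore space in %, from volumetric moisture in %.

    Linear in θ; increasing in ρb (denser soil → less pore volume →
    the same water fills more of it). θ equal to total porosity × 100
    gives exactly 100% (saturation).
    """
    if not 0 < rho_b < rho_p:
        raise PorosityError(
            f"require 0 < bulk density ({rho_b}) < particle density ({rho_p})")
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("volumetric moisture must be >= 0")
    porosity = 1.0 - rho_b / rho_p
    out = theta / porosity
    return float(out) if out.ndim == 0 else out


def gravimetric_to_volumetric(theta_g: float, rho_b: float) -> float:
    """θv = θg · ρb (water density 1 g cm⁻³); both moisture contents in %."""
    return theta_g * rho_b


def iwp(Y: float, I_mm: float) -> float | Undefined:
    """Irrigation water productivity, kg m⁻³.

    ``I_mm`` is the irrigation depth in mm; 1 mm over 1 ha is 10 m³, so
    IWP = Y / (10 · I_mm). Undefined for rain-fed (zero-irrigation) plots.
    """
    if I_mm < 0 or Y < 0:
        raise ValueError("yield and irrigation must be >= 0")
    if I_mm == 0:
        return UNDEFINED
    return Y / (10.0 * I_mm)


def pfpn(Y: float, N: float) -> float | Undefined:
    """Partial factor productivity of nitrogen, kg hay per kg N.

    Undefined for unfertilized plots.
    """
    if N < 0 or Y < 0:
        raise ValueError("yield and nitrogen rate must be >= 0")
    if N == 0:
        return UNDEFINED
    return Y / N


def annual_yield(per_harvest: "list[float] | tuple[float, ...]") -> float:
    """Season total over harvest cuts."""
    return float(np.sum(per_harvest))
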