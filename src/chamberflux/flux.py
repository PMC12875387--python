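"""Chamber flux estimation.

Converts GC peak areas to concentrations against a certified standard,
fits the linear concentration-vs-time slope of a closed-chamber series,
and scales the slope to an areal flux with the ideal-gas chamber formula

    F = (M / 22.4) · (273 / (273 + Ta)) · 60 · H · dC/dt

where M is the molar mass (g mol⁻¹), Ta the chamber air temperature (°C),
H the chamber height (m) and dC/dt the regression slope in nL L⁻¹ min⁻¹
(N₂O, CH₄) or µL L⁻¹ min⁻¹ (CO₂). The 22.4 L mol⁻¹ molar volume assumes
1 atm; the factor 60 converts per-minute slopes to per-hour fluxes.
Resulting units are µg m⁻² h⁻¹ (N₂O, CH₄) or mg m⁻² h⁻¹ (CO₂); negative
fluxes (soil uptake) are preserved.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .campaign import (
    ChamberSeries,
    FluxRecord,
    Gas,
    MassBasis,
    QCFlag,
    QCThresholds,
    SeriesMode,
    StandardGas,
)

__all__ = [
    "peak_area_to_concentration",
    "estimate_slope",
    "flux_from_slope",
    "qc_classify",
    "estimate_flux",
]

MOLAR_VOLUME_STP = 22.4  # L mol⁻¹ at 0 °C, 1 atm


class InvalidStandardError(ValueError):
    pass


class InsufficientSamplesError(ValueError):
    pass


def peak_area_to_concentration(A_S, standard: StandardGas):
    """Concentration of a sample from its GC peak area: C_S = A_S · C0 / A0.

    Linear single-point calibration against the certified standard.
    Accepts scalars or arrays; units follow ``certified_concentration_C0``.
    """
    if standard.peak_area_A0 <= 0:
        raise InvalidStandardError("standard peak area A0 must be positive")
    A_S = np.asarray(A_S, dtype=float)
    if np.any(A_S < 0):
        raise ValueError("peak areas must be >= 0")
    out = A_S * standard.certified_concentration_C0 / standard.peak_area_A0
    return float(out) if out.ndim == 0 else out


def estimate_slope(series: ChamberSeries,
                   standard: StandardGas | None = None) -> tuple[float, float, int]:
    """OLS slope of concentration vs elapsed minutes for one deployment.

    Returns ``(slope, r_squared, n_points)`` with the slope in the gas's
    dC/dt unit. Peak-area series are converted through the standard
    first. For an exactly flat series the slope is 0 and r² is reported
    as 1.0 (a perfectly explained zero trend, which QC treats through the
    near-zero-slope band rather than the r² rule).
    """
    times = np.array([t for t, _ in series.samples])
    values = np.array([v for _, v in series.samples])
    if series.mode is SeriesMode.PEAK_AREA:
        if standard is None:
            raise InvalidStandardError("peak-area series require a StandardGas")
        values = peak_area_to_concentration(values, standard)
    n = len(times)
    if n < 3:
        raise InsufficientSamplesError(f"need >= 3 samples, got {n}")
    if np.ptp(times) == 0:
        raise ValueError("zero time variance")
    res = stats.linregress(times, values)
    r2 = res.rvalue ** 2
    if np.allclose(values, values[0]):
        # linregress yields r = nan for a constant response
        return 0.0, 1.0, n
    return float(res.slope), float(r2), n


def flux_from_slope(slope: float, gas: Gas, Ta: float, H: float,
                    basis: MassBasis = MassBasis.GAS) -> float:
    """Areal flux from a concentration slope via the chamber formula.

    Exact closed form, linear in both ``slope`` and ``H``; decreasing in
    ``Ta`` (denser air holds less gas per headspace volume). ``basis``
    selects the molar mass: gas-mass by default, element-mass (N or C)
    when the downstream accounting wants element fluxes directly.
    """
    if Ta <= -273.0:
        raise ValueError("chamber temperature must exceed -273 °C")
    if H <= 0:
        raise ValueError("chamber height must be positive")
    M = gas.molar_mass(basis)
    return (M / MOLAR_VOLUME_STP) * (273.0 / (273.0 + Ta)) * 60.0 * H * slope


def qc_classify(slope: float, r_squared: float, n_points: int,
                thresholds: QCThresholds = QCThresholds()) -> QCFlag:
    """Deterministic QC rule for a fitted chamber regression.

    Pass when n ≥ min_points and either r² clears the threshold or the
    slope sits in the near-zero band (flat series legitimately have
    meaningless r²); otherwise the series is flagged nonlinear.
    """
    if n_points < thresholds.min_points:
        return QCFlag.INSUFFICIENT
    if r_squared >= thresholds.r2_min or abs(slope) <= thresholds.near_zero_slope:
        return QCFlag.PASS
    return QCFlag.NONLINEAR


def estimate_flux(series: ChamberSeries,
                  standard: StandardGas | None = None,
                  thresholds: QCThresholds = QCThresholds(),
                  basis: MassBasis = MassBasis.GAS) -> FluxRecord:
    """Full per-deployment pipeline: slope fit, flux scaling, QC flag."""
    try:
        slope, r2, n = estimate_slope(series, standard)
    except InsufficientSamplesError:
        return FluxRecord(series.plot_id, series.gas, series.deployment_time,
                          float("nan"), float("nan"), float("nan"),
                          series.n_samples, QCFlag.INSUFFICIENT)
    F = flux_from_slope(slope, series.gas, series.chamber_air_temp_Ta,
                        series.chamber_height_H, basis)
    flag = qc_classify(slope, r2, n, thresholds)
    return FluxRecord(series.plot_id, series.gas, series.deployment_time,
                      F, slope, r2, n, flag)
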