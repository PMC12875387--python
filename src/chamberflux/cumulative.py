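"""Cumulative emission integration.

Seasonal and per-harvest cumulative emissions are the trapezoid sum over
consecutive flux measurements,

    GF = Σ (F_{i+1} + F_i) / 2 · (t_{i+1} − t_i) · 24 · K,

with t in days, the factor 24 converting day intervals to the hourly flux
basis, and K the per-gas unit factor (10⁻⁵ for the µg-flux gases N₂O and
CH₄, 10⁻² for CO₂), giving kg ha⁻¹ on the gas-mass basis. The default
element basis multiplies by the gas's element mass fraction (28/44 for
N₂O → kg N ha⁻¹; 12/44 and 12/16 for CO₂/CH₄ → kg C ha⁻¹).

This is exactly the integral of the piecewise-linear interpolant through
the measurements, which is what makes harvest-cycle partitioning additive:
cutting the season at interior boundaries (interpolating the boundary
flux where no measurement coincides) recovers the seasonal total exactly.
No extrapolation happens beyond the first or last measurement.
"""

from __future__ import annotations

import datetime as _dt
from typing import Iterable, Sequence

import numpy as np

from .campaign import (
    CumulativeEmission,
    FluxRecord,
    Gas,
    ManagementEvent,
    MassBasis,
    QCFlag,
)

__all__ = [
    "cumulate",
    "partition_by_harvest",
    "event_window_share",
    "InsufficientCoverageError",
]

HOURS_PER_DAY = 24.0


class InsufficientCoverageError(ValueError):
    """Fewer than two usable flux measurements inside the interval."""


class UndefinedRatioError(ZeroDivisionError):
    """Event-window share is undefined when the seasonal total is zero."""


def _as_day(ts) -> float:
    """Timestamp → fractional days since an arbitrary fixed epoch."""
    if isinstance(ts, _dt.datetime):
        return ts.timestamp() / 86400.0
    if isinstance(ts, _dt.date):
        return _dt.datetime(ts.year, ts.month, ts.day).timestamp() / 86400.0
    return float(ts)


def _usable(fluxes: Iterable[FluxRecord]) -> list[FluxRecord]:
    return [f for f in fluxes if f.qc_flag is QCFlag.PASS]


def _series_arrays(fluxes: Sequence[FluxRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([_as_day(f.time) for f in fluxes])
    F = np.array([f.flux_F for f in fluxes])
    if np.any(np.diff(t) <= 0):
        raise ValueError("flux record times must be strictly increasing")
    return t, F


def _interp_integral(t: np.ndarray, F: np.ndarray, a: float, b: float) -> float:
    """∫ over [a, b] of the piecewise-linear interpolant, clipped to the data range.

    Units: flux unit × days.
    """
    a = max(a, t[0])
    b = min(b, t[-1])
    if b <= a:
        return 0.0
    # knots strictly inside plus interpolated endpoints
    inside = t[(t > a) & (t < b)]
    knots = np.concatenate(([a], inside, [b]))
    vals = np.interp(knots, t, F)
    return float(np.trapezoid(vals, knots))


def _mass_factor(gas: Gas, basis: MassBasis) -> float:
    factor = HOURS_PER_DAY * gas.unit_factor_K
    if basis is MassBasis.ELEMENT:
        factor *= gas.element_fraction
    return factor


def cumulate(fluxes: Sequence[FluxRecord],
             interval: tuple | None = None,
             basis: MassBasis = MassBasis.ELEMENT,
             subject_id: str | None = None) -> CumulativeEmission:
    """Trapezoid-integrate one plot+gas flux series over an interval.

    ``fluxes`` must be time-ordered records of a single gas; only
    pass-QC records are used, and records outside ``interval`` are
    excluded. The interval defaults to the span of the usable records.
    ``basis`` selects element-mass (default; kg N or kg C ha⁻¹) or
    gas-mass output.
    """
    usable = _usable(fluxes)
    if len(usable) < 2:
        raise InsufficientCoverageError(
            f"need >= 2 pass-QC flux records, got {len(usable)}")
    gas = usable[0].gas
    if any(f.gas is not gas and f.gas.name != gas.name for f in usable):
        raise ValueError("cumulate expects records of a single gas")
    t, F = _series_arrays(usable)

    if interval is None:
        a, b = t[0], t[-1]
        start_d = usable[0].time
        end_d = usable[-1].time
    else:
        start_d, end_d = interval
        a, b = _as_day(start_d), _as_day(end_d)
        n_outside = int(np.sum((t < a) | (t > b)))
        if len(t) - n_outside < 2:
            raise InsufficientCoverageError(
                f"need >= 2 pass-QC flux records inside the interval, "
                f"got {len(t) - n_outside}")

    integral = _interp_integral(t, F, a, b)
    GF = integral * _mass_factor(gas, basis)
    start_date = start_d.date() if isinstance(start_d, _dt.datetime) else start_d
    end_date = end_d.date() if isinstance(end_d, _dt.datetime) else end_d
    n_in = int(np.sum((t >= a) & (t <= b)))
    return CumulativeEmission(subject_id or usable[0].plot_id, gas,
                              (start_date, end_date), GF, n_in, basis)


def partition_by_harvest(fluxes: Sequence[FluxRecord],
                         harvest_dates: Sequence[_dt.date],
                         season: tuple | None = None,
                         basis: MassBasis = MassBasis.ELEMENT,
                         subject_id: str | None = None) -> list[CumulativeEmission]:
    """Split the seasonal integral into contiguous harvest-cycle integrals.

    Intervals are (start, h1], (h1, h2], ..., (h_last, end] with the
    season start closed. Boundary fluxes are linearly interpolated where
    no measurement falls exactly on a harvest date, so the per-cycle
    values sum to the seasonal total exactly.
    """
    usable = _usable(fluxes)
    if len(usable) < 2:
        raise InsufficientCoverageError("need >= 2 pass-QC flux records")
    gas = usable[0].gas
    t, F = _series_arrays(usable)
    if season is None:
        lo, hi = t[0], t[-1]
        season_dates = (usable[0].time, usable[-1].time)
    else:
        lo, hi = _as_day(season[0]), _as_day(season[1])
        season_dates = season

    hd = sorted(harvest_dates)
    if any(not (lo <= _as_day(d) <= hi) for d in hd):
        raise ValueError("harvest dates must fall inside the season")
    bounds = [lo] + [_as_day(d) for d in hd] + [hi]
    # drop a trailing duplicate when the last harvest is the season end
    edges = [bounds[0]]
    for b in bounds[1:]:
        if b > edges[-1]:
            edges.append(b)

    sid = subject_id or usable[0].plot_id
    out = []
    date_edges = [season_dates[0]] + list(hd) + [season_dates[1]]
    date_edges = [d.date() if isinstance(d, _dt.datetime) else d for d in date_edges]
    de = [date_edges[0]]
    for d in date_edges[1:]:
        if d > de[-1]:
            de.append(d)
    for i in range(len(edges) - 1):
        a, b = edges[i], edges[i + 1]
        integral = _interp_integral(t, F, a, b)
        GF = integral * _mass_factor(gas, basis)
        n_in = int(np.sum((t >= a) & (t <= b)))
        out.append(CumulativeEmission(sid, gas, (de[i], de[i + 1]), GF, n_in, basis))
    return out


def event_window_share(fluxes: Sequence[FluxRecord],
                       events: Sequence[ManagementEvent | _dt.date],
                       window_days: float = 7.0) -> float:
    """Fraction of the seasonal cumulative emission inside post-event windows.

    Each event opens a window of ``window_days`` after its date;
    overlapping windows are merged before integrating, so no mass is
    double-counted. With all fluxes ≥ 0 the share lies in [0, 1].
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    usable = _usable(fluxes)
    if len(usable) < 2:
        raise InsufficientCoverageError("need >= 2 pass-QC flux records")
    t, F = _series_arrays(usable)
    total = _interp_integral(t, F, t[0], t[-1])
    if total == 0:
        raise UndefinedRatioError("seasonal cumulative emission is zero")
    starts = sorted(_as_day(e.date if isinstance(e, ManagementEvent) else e) for e in events)
    merged: list[list[float]] = []
    for s in starts:
        e = s + window_days
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    inside = sum(_interp_integral(t, F, a, b) for a, b in merged)
    return inside / total
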