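"""CSV and configuration file schemas.

All tables are UTF-8 CSV with a header row, ISO-8601 dates, and explicit
unit columns where a silent basis mix-up would be costly. Undefined
metric cells (unfertilized PFPN/EF, unirrigated IWP) are written as the
en-dash token "–" and read back as the UNDEFINED marker, never as 0.

Schemas
-------
chamber series : plot, gas, deployment_time, elapsed_min, value, mode,
                 chamber_height_m, chamber_air_temp_C   (one row per syringe)
soil           : plot, time, soil_temp_C, theta_volumetric_pct,
                 bulk_density_g_cm3, particle_density_g_cm3, available_N_mg_kg
fluxes         : plot, gas, time, flux, flux_unit, slope, slope_unit,
                 r_squared, n_points, qc_flag
cumulative     : treatment, plot, gas, harvest, GF, unit, n_measurements
yields         : treatment, plot, harvest, yield_kg_ha
metrics        : treatment, yield_kg_ha, IWP_kg_m3, PFPN_kg_kg, EF_pct,
                 GWP_soil, GWP_inputs, GWP_total, GHGI
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .campaign import (
    GASES,
    CampaignConfig,
    ChamberSeries,
    EventKind,
    FluxRecord,
    ManagementEvent,
    MassBasis,
    QCFlag,
    QCThresholds,
    SeriesMode,
    SoilObservation,
    Treatment,
    TreatmentMetrics,
    UNDEFINED,
    Undefined,
)

__all__ = [
    "UNDEFINED_TOKEN",
    "SchemaError",
    "write_chamber_series", "read_chamber_series",
    "write_soil_observations", "read_soil_observations",
    "write_fluxes", "read_fluxes",
    "write_yields", "read_yields",
    "write_metrics", "read_metrics",
    "write_config", "read_config",
    "config_hash",
]

UNDEFINED_TOKEN = "–"  # en dash, as field reports print it


class SchemaError(ValueError):
    """A table did not match its documented schema; names column and row."""


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {', '.join(missing)}")


def _parse_datetime(value, what: str, row: int) -> _dt.datetime:
    try:
        return _dt.datetime.fromisoformat(str(value))
    except ValueError as exc:
        raise SchemaError(f"{what}: row {row}: malformed date {value!r}") from exc


def _fmt(value) -> str:
    if isinstance(value, Undefined) or value is None:
        return UNDEFINED_TOKEN
    return repr(float(value))


def _unfmt(value):
    if isinstance(value, str) and value.strip() == UNDEFINED_TOKEN:
        return UNDEFINED
    if pd.isna(value):
        return UNDEFINED
    return float(value)


# --- chamber series ---------------------------------------------------------

def write_chamber_series(series: Sequence[ChamberSeries], path) -> None:
    rows = []
    for s in series:
        for t, v in s.samples:
            rows.append({
                "plot": s.plot_id, "gas": s.gas.name,
                "deployment_time": s.deployment_time.isoformat(),
                "elapsed_min": t, "value": repr(v), "mode": s.mode.value,
                "chamber_height_m": s.chamber_height_H,
                "chamber_air_temp_C": s.chamber_air_temp_Ta,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_chamber_series(path) -> list[ChamberSeries]:
    df = pd.read_csv(path, dtype={"value": float}, float_precision="round_trip")
    _require_columns(df, ["plot", "gas", "deployment_time", "elapsed_min",
                          "value", "mode", "chamber_height_m", "chamber_air_temp_C"],
                     "chamber series")
    out = []
    for (plot, gas, when), grp in df.groupby(["plot", "gas", "deployment_time"], sort=False):
        row0 = int(grp.index[0])
        if gas not in GASES:
            raise SchemaError(f"chamber series: row {row0}: unknown gas {gas!r}")
        dt = _parse_datetime(when, "chamber series", row0)
        samples = tuple(zip(grp["elapsed_min"].astype(float), grp["value"].astype(float)))
        out.append(ChamberSeries(
            str(plot), GASES[gas], dt, samples,
            chamber_height_H=float(grp["chamber_height_m"].iloc[0]),
            chamber_air_temp_Ta=float(grp["chamber_air_temp_C"].iloc[0]),
            mode=SeriesMode(grp["mode"].iloc[0])))
    return out


# --- soil observations ------------------------------------------------------

def write_soil_observations(obs: Sequence[SoilObservation], path) -> None:
    pd.DataFrame([{
        "plot": o.plot_id, "time": o.time.isoformat(),
        "soil_temp_C": o.soil_temp, "theta_volumetric_pct": o.theta_volumetric,
        "bulk_density_g_cm3": o.bulk_density_rho_b,
        "particle_density_g_cm3": o.particle_density_rho_p,
        "available_N_mg_kg": o.available_N,
    } for o in obs]).to_csv(path, index=False)


def read_soil_observations(path) -> list[SoilObservation]:
    df = pd.read_csv(path)
    _require_columns(df, ["plot", "time", "soil_temp_C", "theta_volumetric_pct",
                          "bulk_density_g_cm3", "particle_density_g_cm3",
                          "available_N_mg_kg"], "soil observations")
    return [SoilObservation(
        str(r.plot), _parse_datetime(r.time, "soil observations", i),
        float(r.soil_temp_C), float(r.theta_volumetric_pct),
        float(r.bulk_density_g_cm3), float(r.particle_density_g_cm3),
        float(r.available_N_mg_kg))
        for i, r in enumerate(df.itertuples(index=False))]


# --- fluxes -----------------------------------------------------------------

def write_fluxes(records: Sequence[FluxRecord], path) -> None:
    pd.DataFrame([{
        "plot": r.plot_id, "gas": r.gas.name, "time": r.time.isoformat(),
        "flux": repr(r.flux_F), "flux_unit": r.gas.flux_unit,
        "slope": repr(r.slope_dCdt), "slope_unit": r.gas.slope_unit,
        "r_squared": r.r_squared, "n_points": r.n_points,
        "qc_flag": r.qc_flag.value,
    } for r in records]).to_csv(path, index=False)


def read_fluxes(path) -> list[FluxRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["plot", "gas", "time", "flux", "slope",
                          "r_squared", "n_points", "qc_flag"], "fluxes")
    out = []
    for i, r in enumerate(df.itertuples(index=False)):
        if r.gas not in GASES:
            raise SchemaError(f"fluxes: row {i}: unknown gas {r.gas!r}")
        out.append(FluxRecord(
            str(r.plot), GASES[r.gas], _parse_datetime(r.time, "fluxes", i),
            float(r.flux), float(r.slope), float(r.r_squared),
            int(r.n_points), QCFlag(r.qc_flag)))
    return out


# --- yields -----------------------------------------------------------------

def write_yields(yields: pd.DataFrame, path) -> None:
    _require_columns(yields, ["treatment", "plot", "harvest", "yield_kg_ha"], "yields")
    yields.to_csv(path, index=False)


def read_yields(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["treatment", "plot", "harvest", "yield_kg_ha"], "yields")
    return df


# --- metrics ----------------------------------------------------------------

_METRIC_COLUMNS = ["treatment", "yield_kg_ha", "IWP_kg_m3", "PFPN_kg_kg",
                   "EF_pct", "GWP_soil", "GWP_inputs", "GWP_total", "GHGI"]


def write_metrics(metrics: Sequence[TreatmentMetrics], path) -> None:
    """Annual treatment metrics; undefined cells rendered as "–"."""
    rows = [{
        "treatment": m.treatment_id, "yield_kg_ha": _fmt(m.yield_Y),
        "IWP_kg_m3": _fmt(m.IWP), "PFPN_kg_kg": _fmt(m.PFPN),
        "EF_pct": _fmt(m.EF_pct), "GWP_soil": _fmt(m.GWP_soil),
        "GWP_inputs": _fmt(m.GWP_inputs), "GWP_total": _fmt(m.GWP_total),
        "GHGI": _fmt(m.GHGI),
    } for m in metrics]
    pd.DataFrame(rows, columns=_METRIC_COLUMNS).to_csv(path, index=False)


def read_metrics(path) -> list[TreatmentMetrics]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _METRIC_COLUMNS, "metrics")
    out = []
    for r in df.itertuples(index=False):
        out.append(TreatmentMetrics(
            treatment_id=r.treatment,
            yield_Y=_unfmt(r.yield_kg_ha),
            IWP=_unfmt(r.IWP_kg_m3), PFPN=_unfmt(r.PFPN_kg_kg),
            EF_pct=_unfmt(r.EF_pct),
            GWP_soil=_unfmt(r.GWP_soil), GWP_inputs=_unfmt(r.GWP_inputs),
            GWP_total=_unfmt(r.GWP_total), GHGI=_unfmt(r.GHGI)))
    return out


# --- configuration ----------------------------------------------------------

def _config_to_dict(config: CampaignConfig) -> dict:
    return {
        "design": [{
            "id": t.id,
            "irrigation_per_harvest": list(t.irrigation_per_harvest),
            "nitrogen_rate": t.nitrogen_rate_NF,
            "replicates": list(t.replicates),
        } for t in config.design],
        "calendar": [{
            "date": e.date.isoformat(), "kind": e.kind.value,
            "amount": e.amount, "scope": e.treatment_scope,
        } for e in config.calendar],
        "emission_factors": dict(config.inventory_defaults),
        "qc": dataclasses.asdict(config.qc),
        "mass_basis": config.mass_basis.value,
        "season": [config.season[0].isoformat(), config.season[1].isoformat()],
        "reference_treatment": config.reference_treatment,
        "seed": config.seed,
    }


def write_config(config: CampaignConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=False),
                          encoding="utf-8")


def read_config(path) -> CampaignConfig:
    try:
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise SchemaError(f"config: unreadable YAML in {path}: {exc}") from exc
    try:
        design = [Treatment(d["id"], tuple(d["irrigation_per_harvest"]),
                            float(d["nitrogen_rate"]), tuple(d.get("replicates", ())))
                  for d in data["design"]]
        calendar = [ManagementEvent(_dt.date.fromisoformat(e["date"]),
                                    EventKind(e["kind"]), float(e.get("amount", 0.0)),
                                    e.get("scope", "all"))
                    for e in data.get("calendar", [])]
        return CampaignConfig(
            design=design,
            calendar=calendar,
            inventory_defaults=dict(data.get("emission_factors", {})),
            qc=QCThresholds(**data.get("qc", {})),
            mass_basis=MassBasis(data.get("mass_basis", "element")),
            season=tuple(_dt.date.fromisoformat(d) for d in data["season"]),
            reference_treatment=data.get("reference_treatment", "W2N3"),
            seed=int(data.get("seed", 0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"config: invalid structure in {path}: {exc}") from exc


def config_hash(config: CampaignConfig) -> str:
    """Stable short hash of the full configuration, for run logs."""
    payload = json.dumps(_config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
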