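"""End-to-end campaign analysis.

Chains the stages over a campaign bundle (simulated or loaded from
files): chamber series → QC'd fluxes → per-harvest and seasonal
cumulative emissions per plot → replicate-averaged treatment tables →
resource-efficiency and climate metrics → contrasts against a reference
treatment.
"""

from __future__ import annotations

import datetime as _dt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .campaign import (
    GASES,
    CampaignConfig,
    FluxRecord,
    MassBasis,
    QCFlag,
    QCThresholds,
    Treatment,
    TreatmentMetrics,
    UNDEFINED,
    Undefined,
)
from .climate import (
    allocate_inventory_per_harvest,
    contrast,
    emission_factor,
    ghgi,
    gwp_inputs,
    gwp_soil,
    gwp_total,
)
from .cumulative import cumulate, partition_by_harvest
from .flux import estimate_flux
from .productivity import annual_yield, iwp, pfpn
from .simulate import CampaignBundle

__all__ = [
    "estimate_campaign_fluxes",
    "cumulative_table",
    "metrics_from_tables",
    "yields_table",
    "campaign_metrics",
    "contrast_report",
]


def estimate_campaign_fluxes(bundle: CampaignBundle,
                             thresholds: QCThresholds = QCThresholds()
                             ) -> dict[tuple[str, str], list[FluxRecord]]:
    """Fit every chamber deployment of the bundle; key: (plot, gas name)."""
    return {
        key: [estimate_flux(s, thresholds=thresholds) for s in series_list]
        for key, series_list in bundle.chamber_series.items()
    }


def cumulative_table(flux_records: Mapping[tuple[str, str], Sequence[FluxRecord]],
                     design: Sequence[Treatment],
                     harvest_dates: Sequence[_dt.date],
                     season: tuple[_dt.date, _dt.date] | None = None,
                     basis: MassBasis = MassBasis.ELEMENT) -> pd.DataFrame:
    """Per-plot cumulative emissions by harvest cycle and season.

    Columns: treatment, plot, gas, harvest (1-based; 0 = whole season),
    GF (kg N or kg C ha⁻¹ on the element basis), n_measurements.
    Integration covers each plot's sampled span (no extrapolation beyond
    the first or last pass-QC record), so the season row is exactly the
    sum of the harvest-cycle rows; ``season`` is accepted for interface
    symmetry but the sampled span governs.
    """
    rows = []
    for tr in design:
        for plot in tr.replicates:
            for gas_name in GASES:
                records = flux_records.get((plot, gas_name))
                if not records:
                    continue
                season_emission = cumulate(records, basis=basis)
                rows.append((tr.id, plot, gas_name, 0,
                             season_emission.GF, season_emission.n_measurements))
                # QC can nibble a plot's first/last record, so only
                # boundaries inside the usable span partition the series;
                # harvest numbering stays aligned with the full calendar
                usable = [r for r in records if r.qc_flag is QCFlag.PASS]
                lo, hi = usable[0].time.date(), usable[-1].time.date()
                hd = sorted(harvest_dates)
                hd_in = [d for d in hd if lo <= d <= hi]
                parts = partition_by_harvest(records, hd_in, basis=basis)
                first_idx = hd.index(hd_in[0]) if hd_in else len(hd)
                for k, part in enumerate(parts):
                    rows.append((tr.id, plot, gas_name, first_idx + k + 1,
                                 part.GF, part.n_measurements))
    return pd.DataFrame(rows, columns=["treatment", "plot", "gas", "harvest",
                                       "GF", "n_measurements"])


def _treatment_means(cum: pd.DataFrame) -> pd.DataFrame:
    g = cum.groupby(["treatment", "gas", "harvest"])["GF"]
    out = g.agg(GF="mean", GF_se=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0)
    return out.reset_index()


def metrics_from_tables(cum: pd.DataFrame,
                        yields: pd.DataFrame,
                        design: Sequence[Treatment],
                        config: CampaignConfig | None = None,
                        weighting_basis: MassBasis = MassBasis.ELEMENT
                        ) -> tuple[pd.DataFrame, list[TreatmentMetrics]]:
    """Metrics from tabular inputs (the CSV-facing core).

    ``cum`` is a per-plot cumulative table as produced by
    :func:`cumulative_table`; ``yields`` has columns
    (treatment, plot, harvest, yield_kg_ha) with 1-based harvests.
    Returns ``(per_harvest, annual)``: a per-treatment × per-harvest
    table (yield, IWP, GWP soil/inputs/total, GHGI) and the annual
    TreatmentMetrics list (adds PFPN and the N₂O emission factor, paired
    with the unfertilized control at the same irrigation level).
    """
    config = config or CampaignConfig(design=list(design))
    means = _treatment_means(cum)

    def gf(treatment_id: str, gas: str, harvest: int) -> float:
        sel = means[(means.treatment == treatment_id) & (means.gas == gas)
                    & (means.harvest == harvest)]
        return float(sel.GF.iloc[0]) if len(sel) else 0.0

    # seasonal N2O of the same-irrigation unfertilized control, for EF pairing
    n0_gf = {w: gf(f"{w}N0", "N2O", 0) for w in {t.water_level for t in design}}
    y_means = yields.groupby(["treatment", "harvest"])["yield_kg_ha"].mean()

    rows = []
    annual: list[TreatmentMetrics] = []
    for tr in design:
        n_cycles = len(tr.irrigation_per_harvest)
        y_harvest = tuple(float(y_means.get((tr.id, h), 0.0))
                          for h in range(1, n_cycles + 1))
        y_annual = annual_yield(y_harvest)
        inventory = config.inventory_for(tr)
        inv_parts = allocate_inventory_per_harvest(inventory, tr)

        soil_parts, input_parts = [], []
        for h in range(1, n_cycles + 1):
            soil = gwp_soil(gf(tr.id, "N2O", h), gf(tr.id, "CH4", h),
                            MassBasis.ELEMENT, weighting_basis)
            inputs = gwp_inputs(inv_parts[h - 1])
            total = gwp_total(soil, inputs)
            w_iwp = iwp(y_harvest[h - 1], tr.irrigation_per_harvest[h - 1])
            rows.append({
                "treatment": tr.id, "harvest": h,
                "yield": y_harvest[h - 1], "IWP": w_iwp,
                "GWP_soil": soil, "GWP_inputs": inputs, "GWP_total": total,
                "GHGI": ghgi(total, y_harvest[h - 1]),
            })
            soil_parts.append(soil)
            input_parts.append(inputs)

        soil_a, inputs_a = sum(soil_parts), sum(input_parts)
        total_a = gwp_total(soil_a, inputs_a)
        ef = (emission_factor(gf(tr.id, "N2O", 0), n0_gf[tr.water_level],
                              tr.nitrogen_rate_NF)
              if tr.nitrogen_rate_NF > 0 else UNDEFINED)
        annual.append(TreatmentMetrics(
            treatment_id=tr.id,
            yield_Y=y_annual,
            yield_per_harvest=y_harvest,
            IWP=iwp(y_annual, tr.irrigation_total_I),
            PFPN=pfpn(y_annual, tr.nitrogen_rate_NF),
            EF_pct=ef,
            GWP_soil=soil_a, GWP_inputs=inputs_a, GWP_total=total_a,
            GHGI=ghgi(total_a, y_annual),
        ))
    return pd.DataFrame(rows), annual


def yields_table(bundle: CampaignBundle) -> pd.DataFrame:
    """Per-plot per-harvest yields of a bundle as a tidy table."""
    rows = [(tid, plot, h + 1, y)
            for tid, per_plot in bundle.yields.items()
            for plot, vals in per_plot.items()
            for h, y in enumerate(vals)]
    return pd.DataFrame(rows, columns=["treatment", "plot", "harvest", "yield_kg_ha"])


def campaign_metrics(bundle: CampaignBundle,
                     config: CampaignConfig | None = None,
                     thresholds: QCThresholds | None = None,
                     weighting_basis: MassBasis = MassBasis.ELEMENT
                     ) -> tuple[pd.DataFrame, list[TreatmentMetrics]]:
    """Full metric computation for one simulated or assembled campaign."""
    config = config or CampaignConfig(design=bundle.design)
    thresholds = thresholds or config.qc
    flux_records = estimate_campaign_fluxes(bundle, thresholds)
    cum = cumulative_table(flux_records, bundle.design, bundle.harvest_dates,
                           config.season, config.mass_basis)
    return metrics_from_tables(cum, yields_table(bundle), bundle.design,
                               config, weighting_basis)


_REDUCTION_METRICS = ("GWP_soil", "GWP_inputs", "GWP_total", "GHGI", "EF_pct")
_IMPROVEMENT_METRICS = ("yield_Y", "IWP", "PFPN")


def contrast_report(annual: Sequence[TreatmentMetrics],
                    reference_id: str = "W2N3") -> pd.DataFrame:
    """Relative changes of every treatment against the reference.

    Reduction metrics (GWP, GHGI, EF) report (ref−x)/ref·100, so positive
    means the treatment emits less than the reference; improvement
    metrics (yield, IWP, PFPN) report (x−ref)/ref·100. Undefined cells
    stay undefined.
    """
    by_id = {m.treatment_id: m for m in annual}
    if reference_id not in by_id:
        raise KeyError(f"reference treatment {reference_id!r} not in metrics")
    ref = by_id[reference_id]
    rows = []
    for m in annual:
        row: dict = {"treatment": m.treatment_id, "reference": reference_id}
        for name in _REDUCTION_METRICS + _IMPROVEMENT_METRICS:
            a, b = getattr(m, name), getattr(ref, name)
            kind = "reduction" if name in _REDUCTION_METRICS else "improvement"
            if isinstance(a, Undefined) or isinstance(b, Undefined) or b == 0:
                row[f"{name}_{kind}_pct"] = UNDEFINED
            else:
                row[f"{name}_{kind}_pct"] = contrast(a, b, kind)
        rows.append(row)
    return pd.DataFrame(rows)
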