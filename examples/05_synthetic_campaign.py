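"""Simulate a full water x nitrogen campaign and run the whole pipeline.

Generates the 12-treatment x 3-replicate factorial (chamber series, soil
drivers, yields) with event-pulsed N2O, temperature-driven CO2 and a
persistent CH4 sink, then runs flux estimation, cumulative integration
and the climate metrics, and contrasts every treatment against the
conventional high-input reference W2N3.
"""

from chamberflux import SimulationParams, campaign_metrics, contrast_report, simulate_campaign

bundle = simulate_campaign(SimulationParams(seed=7))
print(f"simulated {len(bundle.plots)} plots, "
      f"{sum(len(v) for v in bundle.chamber_series.values())} chamber deployments")

per_harvest, annual = campaign_metrics(bundle)
print(f"{'treatment':<10}{'yield':>9}{'GWP soil':>10}{'GWP inputs':>11}{'GWP total':>11}{'GHGI':>8}")
for m in annual:
    print(f"{m.treatment_id:<10}{m.yield_Y:9.0f}{m.GWP_soil:10.1f}"
          f"{m.GWP_inputs:11.1f}{m.GWP_total:11.1f}{float(m.GHGI):8.1f}")

report = contrast_report(annual, "W2N3")
row = report[report.treatment == "W2N2"].iloc[0]
print(f"\nW2N2 vs W2N3: GWP total {row['GWP_total_reduction_pct']:.1f}% lower, "
      f"yield {row['yield_Y_improvement_pct']:+.1f}%")
# GWP rises with both water and N; the simulated yield optimum under
# full irrigation sits at 120 kg N ha^-1, so the moderate-N treatment
# cuts climate burden without losing yield.
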