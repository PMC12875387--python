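"""Estimate an areal gas flux from one static-chamber deployment.

A closed dark chamber (0.3 m tall) sits on the soil for 30 minutes while
four syringe samples are drawn at 0/10/20/30 min. The N2O concentration
climbs linearly; the OLS slope of concentration vs time, scaled by the
ideal-gas chamber formula, gives the areal flux.
"""

import datetime as dt

from chamberflux import ChamberSeries, N2O, estimate_flux

series = ChamberSeries(
    plot_id="W2N3-r1",
    gas=N2O,
    deployment_time=dt.datetime(2024, 6, 5, 9, 30),
    samples=((0, 331.0), (10, 338.5), (20, 346.1), (30, 353.4)),  # nL L^-1
    chamber_height_H=0.30,
    chamber_air_temp_Ta=24.0,
)

record = estimate_flux(series)
print(f"slope    : {record.slope_dCdt:8.4f} nL L^-1 min^-1")
print(f"r^2      : {record.r_squared:8.5f}  (QC: {record.qc_flag.value})")
print(f"N2O flux : {record.flux_F:8.2f} ug m^-2 h^-1")

# The slope (~0.75 nL/L/min) times (44/22.4)*(273/297)*60*0.3 gives
# ~24 ug N2O m^-2 h^-1 -- a moderate post-fertilization emission pulse.
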