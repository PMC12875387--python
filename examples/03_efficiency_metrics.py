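"""Soil water status and water/nitrogen use efficiency.

WFPS turns volumetric moisture into the fraction of pore space holding
water (the variable that controls nitrification vs denitrification).
IWP and PFPN express yield per unit of irrigation water and fertilizer N;
both are undefined -- not zero -- for plots that received none.
"""

from chamberflux import UNDEFINED, iwp, pfpn, wfps

# study soil: bulk density 1.48 g/cm3, mineral particle density 2.65
theta_fc = 22.4  # volumetric moisture (%) at field capacity
print(f"WFPS at field capacity : {wfps(theta_fc, 1.48, 2.65):.2f} %")

annual_yield = 18907.30  # kg dry hay / ha, high-water moderate-N plot
print(f"IWP  (300 mm season)   : {iwp(annual_yield, 300.0):.3f} kg m^-3")
print(f"PFPN (120 kg N ha^-1)  : {pfpn(annual_yield, 120.0):.2f} kg kg^-1")

rainfed = iwp(11811.79, 0.0)
print(f"IWP of the rain-fed control: {'-' if rainfed is UNDEFINED else rainfed}")
# ~6.3 kg hay per m3 of irrigation water and ~158 kg hay per kg N;
# the rain-fed control has no defined IWP (division by zero water).
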