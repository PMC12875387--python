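# Methods

This note documents the models, unit conventions, numerical choices and
known limitations behind `chamberflux`. It is the package's own account
of its science; every empirical number mentioned here is computed by the
test suite or by `scripts/acceptance.py`.

## Chamber flux model

A static dark chamber of height H traps the soil-emitted gas; under
well-mixed, ideal-gas conditions at 1 atm the headspace concentration
changes linearly at rate dC/dt while the flux is constant, giving

    F = (M / 22.4) · (273 / (273 + Ta)) · 60 · H · dC/dt.

22.4 L mol⁻¹ is the molar volume at 0 °C and 1 atm; the 273/(273+Ta)
factor corrects the gas density to the chamber air temperature; 60
converts per-minute slopes to hourly fluxes. No altitude or headspace
pressure correction is applied, and no nonlinear (saturating) chamber
model is offered: the estimator is exactly the closed form above applied
to the OLS slope of the sampled series (protocol: 0/10/20/30 min).

The molar-mass basis is explicit. Fluxes default to the gas-mass basis
(M = 44, 44, 16 g mol⁻¹ for N₂O, CO₂, CH₄); the element basis
(M = 28, 12, 12 — the N or C contained per mole of gas) is available but
the default pipeline keeps each stage literal and performs the
gas→element conversion once, at the cumulative stage. This makes the
single basis-conversion step auditable instead of smearing it across
stages.

**Quality control.** The trial this package models reports no QC rule,
so the rule here is a package decision, defaulted to common chamber
practice: a deployment passes with n ≥ 3 points and r² ≥ 0.80, with an
exemption band for near-zero slopes (|dC/dt| ≤ 0.1 slope units ≈ 2× the
GC measurement SD propagated to slope units), because a genuinely flat
series has an uninformative r². Duplicated sample times are rejected as
invalid input rather than averaged. Negative fluxes are never truncated:
persistent CH₄ uptake is a finding, not an artifact.

## Cumulative integration

Cumulative emission is the integral of the piecewise-linear interpolant
through the pass-QC measurements (the trapezoid rule), times 24 h/day
and the per-gas unit factor K (10⁻⁵ for µg-flux gases, 10⁻² for the
mg-flux gas), then times the element mass fraction (28/44, 12/44, 12/16)
on the default element basis. Three numerical commitments follow:

- **No extrapolation.** Integration covers each plot's sampled span,
  first to last pass-QC record. The pre-green-up winter gap is not
  back-filled.
- **Exact additivity.** Harvest-cycle intervals are contiguous,
  (start, h₁], (h₁, h₂], …, with boundary fluxes linearly interpolated
  when no measurement falls on a harvest date; per-cycle values
  therefore sum to the season total to machine precision, which the
  tests assert at 1e-9 relative.
- **Oracle equivalence.** The trapezoid equals fine-grid (1-minute)
  rectangle-rule integration of the same interpolant; the acceptance
  script measures the worst relative deviation over 100 random series
  (order 1e-7, bounded by the grid resolution, not the integrator).

Post-event emission shares integrate the same interpolant over the
union of windows (default 7 days, configurable) after irrigation and
fertilization events, merging overlaps so mass is never double-counted.

## Climate accounting

GWP_soil = 265·GF_N₂O + 28·GF_CH₄ (100-year horizon). The weights are
applied by default to the element-basis cumulative emissions exactly as
the integration stage produces them (kg N ha⁻¹, kg C ha⁻¹); a
configuration switch applies them to gas mass instead (×44/28, ×16/12).
Both paths are tested; the literal element-basis reading is the default
because it matches how the accounting chain is defined end to end.
Chamber CO₂ is rejected with an explicit error if offered to the soil
term: dark chambers measure ecosystem respiration without photosynthetic
uptake, so including them would misstate net carbon balance. The
accounting is deliberately a field-gate LCA — machinery manufacture,
transport and soil carbon stock change are out of scope.

GWP_inputs multiplies inventory amounts by fixed upstream emission
factors (N 8.3 kg CO₂-eq kg⁻¹, P₂O₅ 0.79, K₂O 0.55, irrigation 2.66 per
mm, diesel 55.4 per ha, flat). When per-harvest GWP is requested the
inventory is allocated across cycles — N by the 40/30/30% basal/
topdressing split, irrigation by the per-cycle depths, season-wide items
evenly — and the allocation provably cancels in annual totals.

The N₂O emission factor pairs each fertilized treatment with the
unfertilized control **at the same irrigation level**, never a single
global control: irrigation itself shifts background emissions, and the
pairing isolates the fertilizer-induced share. EF, PFPN, IWP and GHGI
are undefined (a dedicated falsy marker, rendered "–") whenever their
denominator input is zero.

## Synthetic campaign generator

The generator is phenomenological by design: daily-scale pulse dynamics,
not process-based biogeochemistry, because the campaign structure it
must emulate is pulse timing, driver windows and sink behavior.

- **Drivers.** Soil temperature is a seasonal sinusoid (mean 17 °C,
  amplitude 13 °C, peak near day-of-year 200, daily observation noise
  1.2 °C). WFPS is a baseline (30%) plus a pulse of 0.45% per mm of
  water input decaying at 0.10 d⁻¹, clipped to [5, 95] — wetter
  treatments therefore span a wider WFPS range. Available mineral N is
  a baseline (22 mg kg⁻¹) plus 1.4 mg kg⁻¹ per kg N ha⁻¹ applied,
  decaying at 0.05 d⁻¹ over a slow season-long drawdown.
- **N₂O** is a base rate (12 µg m⁻² h⁻¹) plus event pulses: amplitude
  4.0 µg per kg N applied (fertilization) or 0.012 µg per mm per
  mg kg⁻¹ available N (wetting), each scaled by a Gaussian moisture
  gain peaking at 50–60% WFPS and decaying at 0.10 d⁻¹ — i.e. fluxes
  stay elevated for one to three weeks after inputs. Because pulse
  amplitudes are frozen at event time, the noise-free seasonal integral
  has an exact closed form, which is the recovery oracle.
- **CO₂** is a Gaussian temperature response peaking at 17.5 °C (width
  12 °C, maximum 520 mg m⁻² h⁻¹) with a mild positive moisture
  modifier. **CH₄** is always uptake, −55 µg m⁻² h⁻¹ at zero WFPS,
  shrinking toward zero as WFPS rises (90% suppression at saturation);
  the mean response never crosses into net emission. Their noise-free
  integrals are evaluated by 0.02-day quadrature (the WFPS clipping and
  temperature coupling have no closed form).
- **Yields** follow a concave water × N response whose N optimum shifts
  from 180 kg ha⁻¹ (rain-fed) down to 120 kg ha⁻¹ under full
  irrigation, split 22.5/46.5/31% across the three cuts, with 4%
  replicate CV. The generator is not calibrated to reproduce any
  measured magnitudes; it reproduces orderings (yield optimum at
  moderate N under high water, weaker CH₄ sink when wetter, GWP rising
  with N).
- **Sampling.** Routine visits every 7 days plus a closing visit on the
  last day; a visit on the morning of each management event (inputs are
  applied midday, after the 9–11 AM chamber window, so that visit reads
  pre-input conditions — without it, interpolation smears pulse mass
  backwards in time); alternate-day visits for 9 days after each
  irrigation/fertilization; a next-day visit after heavy (>10 mm) rain.
- **Noise.** Observed fluxes get mean-one multiplicative lognormal
  noise (log-SD 0.10); chamber concentrations get Gaussian measurement
  noise (1 nL L⁻¹ N₂O, 4 µL L⁻¹ CO₂, 4 nL L⁻¹ CH₄), consistent with
  modern GC repeatability. The trial reports no replicate-level
  variance, so these SDs are free parameters of the generator,
  chosen once so that sampling-plus-noise error at the default density
  stays within the 5% end-to-end recovery budget the pipeline is
  validated against.
- **Seeding.** Every stream derives from (master seed, CRC32(plot id),
  stream index), so campaigns are bit-identical under a fixed seed and
  adding plots never perturbs existing plots' draws.

What passing tests show — and don't. The generator produces linear
chamber series (plus noise), exponential pulses and known driver
couplings, so end-to-end recovery demonstrates that the estimation and
integration chain is unbiased and correctly unit-keyed *under the
assumptions the field method itself makes*. It does not validate those
assumptions against real soils: nonlinear chamber saturation, spatial
heterogeneity, sampling-time-of-day bias and winter emissions are all
outside the generator and therefore outside what the tests can claim.

## Reference tables

`chamberflux.reference` embeds the treatment-level summary results of
the motivating 2023–2024 alfalfa campaign (per-harvest LCA GWP and
GHGI, emission factors, per-harvest IWP and PFPN). They serve as fixed
inputs for table arithmetic — annual totals as per-harvest sums, and
contrasts against the conventional high-input reference W2N3 (the
moderate-N alternative W2N2 computes to a 24.1% lower annual GWP).
Several in-text percentages circulated with that campaign do not
reconcile with its own table arithmetic (EF and GHGI reductions near
29%, efficiency gains of 10.9% and 56.9%); the package implements the
formulas and reports what they give, and does not attempt to force
agreement with irreconcilable summaries. Likewise the campaign's printed
soil/input GWP decomposition cannot be reconstructed exactly from its
printed cumulative fluxes under either mass basis; the residual
(rounding, per-treatment CH₄, allocation) is unknowable from the
published summaries, so no hidden fudge term is introduced.

## Problem sizes

The default simulated campaign is the full study design: 36 plots ×
3 gases × ~50 sampling dates ≈ 5,600 chamber deployments, which the
whole pipeline processes in a few seconds. The acceptance script uses
100 random series for the integrator oracle, 1,000 fluxes for the
chamber round trip, and one full campaign for end-to-end recovery.
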