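# Methods

This note records the scientific and numerical choices behind `maizegap` —
what the model assumes, which knobs matter, what the synthetic data does and
does not emulate, and where the design was genuinely open.

## Scope and model family

The package estimates actual (Ya), water-limited (Yw) and potential (Yp)
grain-maize yields with a *water-driven* crop model: biomass is proportional
to accumulated relative transpiration, not to intercepted radiation. The
engine deliberately follows the AquaCrop family's structure — canopy cover as
the growth state variable, normalized water productivity WP\*, dual
partitioning of evapotranspiration into crop transpiration and soil
evaporation, depletion-based stress coefficients — while remaining a minimal
re-derivation, not a port: one soil layer, overflow drainage, no salinity,
groundwater, capillary rise or curve-number runoff. Behaviour the analysis
relies on is pinned by tests (water-balance closure, regime dominance,
calibration recovery) rather than by fidelity to any reference code.

## Synthetic weather

Real gridded reanalysis/GCM forcing is replaced by a generator whose point is
statistical structure, not realism of any one dataset:

- temperature: annual sinusoid (peak at day 197 in the northern hemisphere)
  plus AR(1) anomalies, `tav = (tmin+tmax)/2` by construction with a fixed
  diurnal range;
- precipitation: two-state wet/dry Markov chain parameterised by the
  stationary wet-day probability and the wet-after-wet persistence, with
  gamma-distributed wet-day amounts (shape 0.8);
- radiation: extraterrestrial radiation for the latitude and day of year,
  times a cloudiness factor of ~0.70 on dry and ~0.40 on wet days with mild
  noise, clipped to 0.10–0.78 of clear sky;
- humidity and wind: noisy stationary series around their means, humidity
  elevated on wet days;
- CO₂: annual resolution (start + linear trend), repeated daily.

Each stochastic component draws from its own seeded substream, which makes
two scenario properties exact rather than statistical: ΔT shifts every
temperature by exactly that amount, and the precipitation factor rescales
every wet-day amount exactly, without disturbing other draws. Ensembles
("GCM-like" members) combine distinct derived seeds with mild perturbations
of the anomaly standard deviation (±10% per level) and wet-day frequency
(±0.02 per level), so members differ in both noise and climatology; member 0
is always the unperturbed spec.

What the generator does **not** emulate: spatially correlated weather across
cells (cells are independent), temperature–radiation–humidity
cross-correlations beyond the wet-day linkage, heat waves and other
extremes clustering, realistic scenario-specific precipitation patterns.
Passing tests therefore demonstrate the *machinery* (calibration, ordering,
signs, accounting) on plausible forcing, not quantitative European yield
values.

Default climatology (annual mean 10.5 °C at the 48 °N reference with a
−0.6 °C/°lat gradient in gridded runs, amplitude 9 °C, wet-day probability
0.35 with persistence 0.6, 5 mm mean wet amount) was chosen once as a
mid-latitude European setting that completes the crop cycle in most years
while leaving room for temperature-limited cells at the cold end of a
gradient.

## Derived drivers

ETo implements the FAO-56 daily Penman–Monteith combination equation for the
grass reference. Choices the equation sheet leaves open, fixed here:

- actual vapour pressure `ea = RH/100 · (es(Tmin)+es(Tmax))/2` — the variant
  for forcing that provides daily-mean relative humidity only;
- 10 m → 2 m wind by the logarithmic profile factor 4.87/ln(67.8·10−5.42)
  ≈ 0.748;
- soil heat flux 0 at daily scale; albedo 0.23; ETo floored at 0;
- relative shortwave Rs/Rso clipped to [0.05, 1]; net longwave floored at 0
  so heavy-overcast days cannot register a radiative *gain* (this also makes
  the degenerate zero-forcing day return exactly 0).

The same conventions are written independently, scalar and line-by-line, in
`tests/fao56_oracle.py`; the suite requires agreement within 0.05 mm/day
over 1000 random days.

GDD uses the mean-temperature form with Tbase 8 °C and Tupper 30 °C.
"Temperatures above Tupper do not contribute" is implemented by *capping*
(GDD = min(Tav, Tupper) − Tbase, floored at 0) rather than by discarding hot
days: discarding would undercount heat precisely on the days that drive
development, and capping preserves monotonicity of accumulated GDD under
uniform warming — the property behind the sowing/cycle warming tests.

## Phenology

Sowing: first day in the 1 March – 29 April window with Tmin strictly above
8 °C on 4 consecutive days ending at (and including) the candidate day; warm
late-February days count toward the run, so an all-warm spring sows on
1 March. If no day qualifies, 29 April. The strict inequality and the
run-ends-at-candidate convention are frozen in tests.

Stages are thresholds on cumulative GDD from sowing, with accumulation
starting the day *after* sowing (the sowing day is day 0). The total cycle
is 1122 °C day; sub-stages default to typical maize fractions — emergence
7%, maximum canopy 60%, flowering 55%, senescence 80% — and are plain
configuration, adjustable per run. Completion is inclusive (exactly
1122 °C day by 31 December completes); the cycle length is counted
emergence → maturity, while completion is assessed from sowing. Both
conventions are explicit in the API.

## Crop engine

Daily loop from sowing until maturity or 31 December:

1. **Soil store.** A single bucket over the full effective rooting depth
   (min of crop and soil maximum, default 1.0 m) holds water between the
   wilting-point and saturation equivalents; rain and irrigation infiltrate,
   excess above saturation drains. Depletion Dr, TAW and RAW for the stress
   coefficients are evaluated over the *current* root depth, which deepens
   from 0.30 m to the maximum in proportion to cumulative GDD up to the
   maximum-canopy threshold. Simulating the full column from day one keeps
   the seasonal balance exactly `P + I + ΔS = Tr + E + D` (the closure test
   requires |residual| < 0.01 mm; in practice it closes to rounding error),
   with root deepening accessing water already in the budget.
2. **Stress.** Ks_sto = 1 while Dr ≤ p_upper·TAW (p_upper 0.55), declining
   linearly to 0 at TAW; Ks_exp analogous with p_lower 0.25 (expansion
   stress starts earlier than stomatal stress).
3. **Canopy.** From emergence (CC₀ = 0.05), logistic growth per GDD at rate
   cgc·Ks_exp toward the ceiling CCx, then exponential decline at cdc per
   GDD after senescence. The transpiring cover uses the micro-advective
   adjustment CC* = 1.72CC − CC² + 0.3CC³.
4. **Fluxes.** Tr = Kc_Tr,x · CC* · ETo · Ks_sto, limited by water above
   wilting point in the root zone; E = Ke_x · (1−CC*) · ETo reduced by a
   two-stage surface-layer limiter (readily evaporable water 9 mm,
   stage-two reduction below half of it).
5. **Biomass.** ΔB = WP\* · f(CO₂) · f_wp,fert · Tr/ETo (skipped when
   ETo = 0), WP\* = 33.7 g/m² — a C4 value.
6. **Harvest index.** Builds linearly in GDD from flowering to maturity up
   to HI₀ = 0.48, then is multiplied by the mean stomatal stress
   coefficient over the flowering window (180 °C day from flowering). This
   pollination-failure penalty is the mechanism that lets a drought reverse
   the fertility advantage (see below); under non-limiting water the
   multiplier is exactly 1.
7. **Irrigation (Yp).** At end of day, if Dr would exceed 50% of RAW, the
   exact depth restoring Dr to that threshold is applied (net requirement,
   no losses). The recorded maximum end-of-day Dr/RAW is therefore ≤ 0.5.

### CO₂ response

`f_co2(c) = 1 + 0.08·(1 − exp(−(c − 369.41)/350))`: continuous,
non-decreasing, equal to 1 at the reference concentration, and saturating at
+8% — a deliberately muted response reflecting maize's C4 pathway (at
550 ppm the factor is ≈1.03). The form and both constants are configurable
arguments; any published alternative can be substituted without interface
change.

### Fertility stress and its calibration

A single stress intensity x ∈ [0, 1] maps to joint reductions
`f_ccx = 1 − 0.50x`, `f_cgc = 1 − 0.30x`, `f_wp = 1 − 0.35x`. The split is a
design choice with a purpose: if fertility only scaled biomass (f_wp alone),
the stressed and unstressed crops would draw down a finite soil store
identically and the water-limited yield could never fall below the actual
yield. Letting the canopy carry half of the stress makes the unstressed
crop's larger canopy deplete the store sooner, so that in terminal-drought
fixtures Yw < Ya — the negative water-limited gap — is reachable, while
Brel targets down to ~45% remain attainable.

The intensity is calibrated by 1-D root finding (Brent, xtol 1e-6) so that
on a fixed internal reference season (constant 19 °C, ETo 4 mm/day, rain
10 mm/day — water never limiting) the stressed/unstressed end-of-season
biomass ratio equals Brel/100. Calibration is deterministic, cached per
(crop, soil, target), and recovers the default 70% target within 0.5
percentage points on independently generated non-limiting seasons; an
unattainable target reports the bracketing interval instead of silently
clamping.

## Gap analysis and statistics

- YGw = (1 − Ya/Yw)·100 and YGp = (1 − Ya/Yp)·100, computed on multi-year
  *mean* yields (per-year series remain available); zero denominators yield
  NaN, never a silent 0. Negative YGw is permitted.
- WP_ET = 100 · yield[ton/ha] / ETc[mm] in kg/m³, with ETc summed from
  emergence to maturity. The per-cell default aggregates the mean over years
  of per-season WP; ratio-of-multi-year-means is exposed as an option.
- Skill metrics: Pearson R, bias = mean(reference − simulated), RMSD.
- Incomplete years are excluded from means and standard deviations
  (interannual SD uses ddof = 1) but counted as crop failures by default;
  both behaviours are switchable.

## Aggregation rules

Ensemble statistic: the median (robust for 5 members; even counts average
the central pair). A cell enters a period's analysis only if *every* member
completed ≥ 5 cycles (inclusive boundary); change maps use the logical AND
of baseline and future masks, while per-scenario maps remain available
unmasked. Suitability uses strict inequalities (< 4 ton/ha unsuitable,
> 7 ton/ha profitable; boundary values are "suitable"), failures are strict
(< 4 ton/ha). Spatial summaries are unweighted means/medians/quartiles
(linear interpolation between order statistics); area weighting was
considered and left out since cells in the small synthetic grids are
comparable, and the summary API accepts any external weighting by masking.

## Pipeline determinism

The global seed feeds a seed sequence with the cell index to give each cell
a base seed; the ensemble generator derives member seeds from it. The
scenario does *not* enter the derivation, so baseline/future pairs share
their weather noise and differ exactly by the scenario deltas — mirroring
how bias-adjusted scenario pairs from one climate model share internal
variability, and sharpening paired comparisons (the warm member of a pair
never sows later than its baseline twin). Re-running a configuration
reproduces every CSV byte-for-byte.

## Problem sizes and tolerances

The shipped experiments are deliberately desk-scale: the end-to-end warming
check uses a 20-cell latitude gradient (40.25–54.5 °N), 5 members, 30 years
and two scenarios (~12 000 simulated seasons, about a minute on one CPU);
unit fixtures use single constant-forcing seasons where closed-form
expectations exist (e.g. 11 GDD/day ⇒ maturity 102 days after sowing).
Boundary tests that probe the inclusive 1122 °C day completion threshold
construct daily increments as dyadic rationals so floating-point summation
is exact. The acceptance script runs a single non-limiting season and
reports the calibrated water-limited gap.

## Known limitations

- No nutrient dynamics beyond the bulk fertility-stress calibration; no
  pests, disease, heat sterility, lodging or flood damage.
- One soil layer and net irrigation only; no application losses, salinity,
  groundwater or runoff routing.
- The weather generator's parameters are free knobs, not estimates fitted to
  any reanalysis; absolute yields are therefore indicative, and the package's
  quantitative claims are confined to relationships the test suite actually
  computes (orderings, calibrated ratios, signs of scenario responses,
  conservation properties).
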