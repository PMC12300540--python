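# Methods

## Index conventions

**Thermal time.** Daily mean temperature is the midrange
`T = (Tmax + Tmin)/2`; no other convention is supported. A day is
*effective* when `T ≥ T0`, with `T0 = 10 °C`, the standard rice base
temperature (configurable). Effective accumulated temperature is
`EAT = Σ (T − T0)` over effective days — note the subtraction of the
base: summing `T` itself would make the use-efficiency ratio
identically 100 %, and only the `(T − T0)` form is consistent with the
photothermal-quotient denominator and reproduces the published
use-efficiency range (51–70 %). Total accumulated temperature is `Σ T`
over effective days, and `TUE = 100·EAT/total`. There is no upper
temperature cap and no hourly interpolation; windows are inclusive on
both ends at daily resolution, and the annual window is the union of
the two contiguous season windows.

**Photothermal quotient.** The daily definition is `S/(T − T0)`. At the
season level the package reports the ratio of totals,
`PQ = Σ S / Σ (T − T0)` over effective days — equivalently mean daily
radiation over mean daily effective temperature. The totals-ratio
choice is validated by reproducing the published 1.26 MJ m⁻² d⁻¹ °C⁻¹
value exactly from the corresponding season totals. Whether the
original analysis averaged daily ratios instead is unknowable from the
published summaries; per-variety season PQs printed only in figures are
therefore not treated as reproduction anchors.

**Degenerate windows.** A window with no effective days has EAT = 0;
TUE and PQ are then NaN-flagged (not exceptions) so batch runs survive
degenerate plots. Missing weather days abort with the first missing
date named; every referential gap across the four input tables is
aggregated into one validation report before the run stops.

**Canopy light.** Interception is computed from one incoming and six
below-canopy light-bar readings (three between rows, three within
rows), averaged with equal weight; values pushed outside [0, 100] by
sensor noise are clamped with a warning. Stage IPAR is the trapezoid
`½(IP_start + IP_end)/100 · f_PAR · SR_stage` with `f_PAR = 0.45`, the
standard PAR fraction of global radiation. Season IPAR partitions the
window into half-open day intervals [start→MT), [MT→PI), [PI→HD),
[HD→MA] (final day included) so every day's radiation is counted
exactly once. Interception at the window start is 0 by default — bare
paddy at transplanting; for the ratoon season the analogous
`rs_initial_ip` is exposed in configuration because high stubble
plausibly intercepts light from day 0, but no measurement anchors a
nonzero default. Stage dates after the window end are refused rather
than extrapolated. The single season-level IP reported in summary
tables is the heading-stage (HD) value, the canonical one-time canopy
interception metric; the per-stage values are all retained in the
index table.

**RUE and annual totals.** `RUE = TDW/IPAR` per season; annual TDW and
IPAR are sums of the season values and annual RUE is the ratio of those
sums, never the mean of season RUEs. Yield is reported at the 14 %
grain-moisture convention; `adjust_yield_moisture` rescales fresh
weights dry-matter-preservingly.

## Split-plot analysis

The layout is the balanced split-plot with replicates as random blocks:
stubble height (whole plot) is tested against the rep × stubble stratum
(Error a, `(r−1)(a−1)` df); variety and variety × stubble (sub plot)
against the residual (Error b, `a(r−1)(b−1)` df). Sums of squares use
the exact balanced mean-decomposition formulas; unbalanced input is a
hard error listing every missing cell. Mean separation uses the
unadjusted LSD at α = 0.05 — the convention of the trials this package
serves, documented here as that convention rather than as best
practice; no multiplicity correction is applied. Three comparison
scopes are first-class: variety means pooled over stubble
(`t_{df_b}·√(2·MS_b/(ra))`), stubble means pooled over variety
(`t_{df_a}·√(2·MS_a/(rb))`), and stubble within a variety, which mixes
strata and uses the combined error `√(2[(b−1)MS_b + MS_a]/(rb))` with
the Satterthwaite-weighted t critical value — the standard balanced
split-plot formula; the exact error term behind the original tables'
within-variety letters is not recoverable from the published material,
and this choice is recorded in output metadata. Compact letter displays
are built by insert-and-absorb on the significance graph; with a single
LSD the graph is an interval graph over the sorted means, so letters
are the maximal runs whose spread does not exceed the LSD. A difference
exactly equal to the LSD is non-significant (strict inequality).
Constant responses report all-zero sums of squares with p = 1; a zero
error mean square under a nonzero effect flags an infinite F; p-values
below machine precision print as `<1e-15`, never 0. Percentage
contrasts are computed on unrounded treatment means; correlations are
Pearson r with the two-sided t test (n − 2 df) and the OLS fit line.
Years are always analysed separately; no pooled-year mode exists.

## Synthetic trial generator

The generator emulates the study conditions the pipeline is designed
for, so that every stage is testable without field data.

**Weather** is plateau-plus-linear-autumn-decline with independent
Gaussian daily noise: defaults of 31.0/22.3 °C (Tmax/Tmin) and
19.0 MJ m⁻² d⁻¹ on the plateau, declining by 0.11 °C d⁻¹ and
0.12 MJ m⁻² d⁻² after day 120 of a 200-day run starting 28 April. Those
values were chosen once so the season means land at the published
subtropical middle-Yangtze climate (≈29.2/20.5 °C, 17.1 MJ m⁻² d⁻¹);
only such seasonal summaries are public, so the simplest shape
reproducing "high summer, declining autumn" is used. Daily noise SDs
default to 1.5 °C and 3.0 MJ m⁻² d⁻¹. Tmin is clamped just below Tmax
on violation and radiation at zero. No rainfall, humidity or wind.

**Trial.** Full factorial 3 reps × {LS, HS} × six varieties whose
main-season durations (99–110 d from transplanting) and base ratoon
durations (54–71 d) bracket realistic middle-Yangtze variety spreads.
Regrowth starts the day after main-season harvest; stage dates (MT, PI,
HD, MA) sit at fixed fractions 0.25/0.5/0.7/1.0 of each window — stage
timing is otherwise unconstrained by published information. High
stubble shortens the ratoon window by 3 days by default and raises the
ratoon interception trajectory (LS 40→55→66→62 %, HS 55→70→80→76 % at
MT/PI/HD/MA; main season 60→82→90→86 % for both). Light-bar rows
realise these trajectories at a 2000-unit incoming intensity with
multiplicative per-reading jitter scaled by `obs_noise_cv`.

**Observations.** Biomass is `RUE_true × IPAR` *by construction* (RUE
2.6 g MJ⁻¹ main season, 2.4 ratoon; no tillering, spikelet or
senescence mechanics), where IPAR is recomputed from the emitted
readings — so with zero noise the pipeline inverts the generator
exactly, and the noise-free parameter-recovery tests are exact rather
than statistical. Yield is `harvest_index × TDW` (harvest index 0.45,
reported in t ha⁻¹ at the 14 % convention). Observation noise is
multiplicative lognormal with mean exactly 1, parameterised by its CV —
multiplicative because biomass and yield are positive with roughly
scale-proportional errors. `obs_noise_cv` has **no default**: the
original trials never report replicate-level variance, so the analyst
must choose it explicitly (tests and examples use 5–8 %).

**Determinism.** Every output is a pure function of (parameters, seed);
per-plot RNG sub-streams are derived from stable
(variety, stubble, rep, season) offsets so adding a variety does not
perturb other plots' draws.

**What passing tests show.** The generator matches the analysis model's
assumptions by construction (normal split-plot errors only
approximately — the noise is lognormal; linear RUE; exact phenology).
Calibration results — the whole-plot F-test rejecting at ≈5 % under the
null, RUE recovered within 3 SE at 5 % CV — therefore validate the
pipeline's statistics and plumbing, not the biological fidelity of any
real trial: real data add measurement error structure, spatial
correlation between plots and genuine variety × weather interaction
that the generator deliberately omits.

## Problem sizes and numerical choices

The test suite exercises: 100-seeded-series brute-force oracle
equivalence for the accumulators (tolerance 1e-9); 500 null trials for
the type-I-error calibration of the whole-plot F-test (99 % binomial
band around 5 %); single-trial parameter recovery at 3 reps and 5 % CV.
These sizes give stable stochastic checks at a few tens of seconds on
one CPU and are fixed in the tests. Reporting-layer rounding matches
the field's table conventions (accumulations, percentages and RUE to
one decimal, PQ to two); all statistics are computed on unrounded
values.

## Known limitations

- One cell of the bundled 2022 reference table is internally
  inconsistent (main-season TDW/IPAR of LY6326 under LS gives 2.67,
  printed RUE 2.6); the reproduction harness reports it as a known
  failure rather than hiding it.
- No mixed-model/REML machinery, heterogeneous variances, or
  Tukey/Bonferroni alternatives to LSD.
- No Beer–Lambert LAI inversion or diurnal light integration; one
  midday light-bar observation per stage is assumed representative.
- The main-season window starts at transplanting (the published figure
  convention); analyses anchored at sowing require shifting the
  phenology input.
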