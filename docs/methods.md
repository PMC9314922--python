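# Methods

This note documents the models and procedures implemented in `isoscape`, the
parameter defaults and why they were chosen, what the synthetic generators
emulate, and the numerical conventions. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## 1. Seal-tooth record

### Correction and QC

Raw replicate δ¹⁵N values of an amino acid are corrected against the nearest
bracketing mixed amino-acid standard:

    reported = mean(replicates) − (standard_measured − standard_known)

Each replicate row carries its own nearest-standard pair (assigned by
injection position, ties to the earlier standard), so instrument drift shared
by a sample and its bracketing standard cancels exactly. Replicate QC follows
laboratory practice for duplicate analysis: a replicate range ≤ 1.0 ‰ passes
with the mean as the final value; a wider range requires a third replicate
(flag `triplicated`, final value the mean of all three); an unresolved wide
duplicate fails QC and is excluded from trend fitting by default (the
threshold and the exclusion are configurable).

### Chronology

Each dentine growth layer group (GLG) records one year of life. The combined
2nd+3rd GLGs of an animal caught in year *c* at age *a* therefore span
calendar years [c−a+1, c−a+2]. Animals younger than 5 years are rejected
(outermost layers incomplete). Because each measurement integrates two years,
the regression abscissa is the **window midpoint**; window start and catch
year are available as alternatives (`abscissa=` in
`SealTrendModel.from_records`). The midpoint convention is a design choice —
nothing in the record constrains it — and with a two-year window it shifts
the intercept, not the slope.

### Trend model

`SealTrendModel` is ordinary least squares of δ¹⁵N_Phe on midpoint year
(Gaussian errors, identity link, no transformation), via `statsmodels.OLS`.
The results object reports the slope per year and per decade with standard
errors, R² (fraction and %), F, degrees of freedom, p-value and residuals.
Residual diagnostics provide the three standard inspection series
(residual–fitted, residual–year, normal QQ) plus numeric tests: Shapiro–Wilk
for normality and Breusch–Pagan for heteroscedasticity, flagged `warn` when
the null is rejected at α (default 0.01). With n < 8 the diagnostics are
marked unreliable. A perfectly constant response has zero centred total sum
of squares; R², F and p are defined as 0, 0 and 1 there rather than trusting
the 0/0 the generic formulas produce.

## 2. Kernel utilization distribution

Fixes are pooled across animals with equal weight per fix (per-animal
weighting is available) and projected onto a Lambert azimuthal equal-area
plane centred on the fix centroid — an equal-area projection is what makes a
metric bandwidth and a probability-per-km² density meaningful. The spherical
projection formulas are implemented directly (sub-metre round trip; a
geodesic oracle test checks 1° of latitude ≈ 111.2 km).

The UD is the bivariate-normal kernel density with bandwidth h = 250 km
(the smoothing used for wide-ranging Barents Sea harp seals), evaluated on a
grid of cell size h/10 padded by 3h, then renormalised so the grid mass is
exactly 1 (the padding leaves <1e-3 off-grid mass). The p-isopleth region is
the highest-density set of grid cells whose accumulated mass first reaches p
— the standard highest-density-region convention — returned as merged cell
polygons in both projected and geographic coordinates. Nesting of isopleths
is automatic (thresholds are monotone in p). Land is not clipped.

**What the UD estimates.** A kernel UD at bandwidth h estimates the *smoothed*
space-use law, not the raw fix-generating density: for fixes drawn from an
isotropic Gaussian with scale σ, the estimand is N(0, σ²+h²), whose 95 %
highest-density region is the disc of area π·χ²₂(0.95)·(σ²+h²). The
calibration tests use exactly this closed form: the fitted 95 % region must
capture 0.95 ± 0.02 of the smoothed law's mass and match the analytic disc
area within 10 %. With h = 250 km ≫ σ the region contains essentially all of
the raw mixture's mass by construction; calibration statements are therefore
made against the smoothed law throughout.

## 3. Deposition forcing

Global reactive-nitrogen deposition is piecewise linear:

* rate(year ≤ 1850) = 11 Tg N yr⁻¹ (preindustrial), in both runs;
* anchors at 1850, 1950, 2000 and 2030, with the 1950 value fixed by the
  constraint that 60 % of the 1850–2000 increase occurs after 1950, i.e.
  rate(1950) = 11 + 0.4·(rate(2000) − 11);
* the control (non-anthropogenic) series holds 11 Tg yr⁻¹ throughout.

The 2000 and 2030 magnitudes are **not** constrained by the printed record:
they default to 2.5× preindustrial at 2000 (deposition to the ocean has more
than doubled since preindustrial times) and 1.08× the 2000 rate at 2030.
Both are configuration, not literature values. Deposited nitrogen carries a
fixed δ¹⁵N of −4 ‰.

The fractions of the global Tg flux reaching the two model boxes
(`regional_scaling_atlantic` = 0.08, `regional_scaling_barents` = 0.02) are
demonstration-scenario values chosen once, during design, so that (i) the
with/without difference in cumulative nitrate delivered to the Barents box
over 1970–2019 is ≈5 % and (ii) the deposition-driven lowering of the
Atlantic endmember is a few hundredths of a permil per decade — the scale of
change the attribution experiment is meant to illustrate. A spatially
resolved model would compute these from deposition maps; a two-box model
cannot, so they are explicit knobs.

The inflow scenario prescribes Atlantic Water transport Q(t) = 2.0 Sv +
0.009 Sv yr⁻¹ ·(t − 1970) (i.e. +0.09 Sv decade⁻¹, the simulated
multi-decadal strengthening of the inflow), inflow nitrate 6 mmol m⁻³, and a
subtropical endmember fraction 0.30 + 0.002 yr⁻¹·(t − 1970) mixing
endmembers at δ¹⁵N_NO3 = 5.0 ‰ (subpolar) and 3.5 ‰ (subtropical) —
literature-style endmember values, exposed as configuration. Mixing is linear
in the volume fraction at equal nitrate concentrations, nitrate-weighted
otherwise.

## 4. Two-box nitrogen-isotope model

### Structure

The minimal topology in which the two competing isotope mechanisms coexist:

* **Atlantic source box** — a nitrate pool (1.2e13 mol, ~10-year turnover via
  a 1.2e12 mol yr⁻¹ exchange with upstream water carrying the
  circulation-driven endmember δ) that also receives its share of
  deposition. Its δ is the inflow endmember delivered to the Barents Sea;
  deposition of −4 ‰ nitrogen lowers it with a realistic multi-year lag.
* **Barents surface box** — a 1.0e12 m² surface (the harp-seal habitat
  scale) over a fixed 100 m mixed layer. Each year, in order: (1) the supply
  pool mixes leftover nitrate, inflow (Q·[NO₃]) and direct deposition;
  (2) a utilisation fraction is consumed, producing POM under closed-system
  Rayleigh fractionation; (3) the POM pool is exported (0.70) and
  remineralised (0.25) with the remainder persisting; (4) through-flow
  flushes residual nitrate (flush fraction = Q·Δt / V, ≈0.65 yr⁻¹ — a
  realistic ~1.5-year residence time).

All isotope bookkeeping is mass-weighted δ mixing (linear-in-δ), accurate to
<0.01 ‰ for δ within ±10 ‰ of air (tested against exact atom-fraction
mixing). Internal transfers conserve Σ(mass·δ) exactly; the closed-system
conservation test holds this to 1e-9 relative over repeated steps.

### Fractionation

Closed-system Rayleigh with ε = 5 ‰ (the canonical nitrate-assimilation
fractionation) is the default, chosen because the seasonal Barents bloom
approaches complete drawdown — the accumulated product is the right
within-year closure:

    δ_POM   = δ_supply + ε · f ln f / (1 − f)
    δ_resid = δ_supply − ε · ln f

with f the fraction of supply remaining. The f→0 limit returns δ_supply
(mass balance) and f→1 returns δ_supply − ε (instantaneous product). The
open-system steady-state form δ_POM = δ_supply − ε·f is implemented as an
alternative (`rayleigh_form="open"`). The mass-balance identity
f·δ_resid + (1−f)·δ_POM = δ_supply holds to 1e-10 ‰ by construction and is
tested over random draws.

### Uptake

Default is Vmax-limited Michaelis–Menten: annual uptake concentration
= Vmax(t)·C/(K+C) with K = 2 mmol m⁻³ and Vmax(t) = 4.0 + 0.022·(t−1970)
mmol m⁻³ yr⁻¹. The linear Vmax increase is a proxy for the lengthening
open-water growing season, the local driver of rising utilisation. Two
properties of this form matter:

* the uptake *amount* is sub-linear in supply (elasticity K/(K+C) < 1), so
  extra deposited nitrate increases production by proportionally less than it
  increases delivery — the NPP attribution is bounded by the nitrate
  attribution, as nitrate-limited uptake requires;
* the utilisation fraction rises with Vmax, which pulls the Rayleigh product
  toward the supply δ and drives the positive δ¹⁵N_POM trend of the
  no-deposition run.

A fixed annual utilisation fraction (`uptake_mode="fraction"`, u(t) = 0.60 +
0.003·(t−1970)) is available for analyses that need utilisation as a direct
control variable (the monotonicity tests use it).

NPP is reported as the carbon equivalent of nitrate uptake at Redfield
C:N = 6.625 divided by the box area (g C m⁻² yr⁻¹); being new-production
based, its magnitude (~20–30 g C m⁻² yr⁻¹) sits below total Barents NPP, as
an f-ratio < 1 implies. Trends and attribution percentages, not magnitudes,
are the model's outputs of interest.

### Spin-up and the paired experiment

Each run repeats the first simulation year's forcing until the largest
year-to-year change in any δ is below 1e-10 ‰ (cap 5000 iterations; failure
raises with diagnostics). The tolerance is tight so that constant-forcing
trends after spin-up are zero to better than 1e-8 ‰ decade⁻¹. The demo
simulation spans 1850–2019 so the deposition ramp acts from its historical
onset; the two runs of the paired experiment differ only in the deposition
switch and are compared over 1970–2019: decadal OLS trends of inflow δ, POM
δ and NPP, plus percent differences in cumulative nitrate delivered and
cumulative NPP. With both regional scalings zero the runs are bit-identical
and all differences are exactly zero.

The control run keeps the preindustrial deposition flux (it is a feature of
the natural nitrogen cycle, not an anthropogenic perturbation), so both runs
share δ_dep; the control is exactly independent of the anthropogenic anchor
magnitudes.

## 5. Section and regional diagnostics

* Atlantic Water: θ > 2 °C **and** S > 34.5 psu, strict inequalities —
  boundary cells are excluded.
* Transport: Σ u·cell_area over masked cells, per year, in Sv.
* Decomposition: Tn(t) = [T(t)/A(t)]·mean(A) carries only velocity changes;
  trend_velocity = decadal OLS trend of Tn and trend_volume = trend_total −
  trend_velocity, so the identity trend_velocity + trend_volume =
  trend_total is exact for every input. Years with an empty AW mask are
  excluded (T/A is undefined); the decomposition requires AW in ≥80 % of
  years and ≥10 years.
* Nitrate flux: Σ [NO₃]·u·cell_area (mol s⁻¹) with an annual cumulative
  integral.
* Masked property means are area-weighted by default; a transport-weighted
  option (weights u·area) represents the value carried by the flow.
* Upper-100 m means: on a 31-level grid the first 10 levels are used
  literally; otherwise all levels whose bottom depth is ≤ 100 m.
  Volume-weighted, with the per-cell series returned for trend mapping.
* NPP integration: vertical integral of volumetric production per column,
  then area-weighted regional mean.
* Decadal trends are plain OLS slopes ×10 with standard errors; no
  autocorrelation correction. Per-cell trend maps report min, max and
  area-weighted mean; cells with missing years are flagged and excluded from
  the summaries.
* Attribution: 100·(with − without)/without, on cumulatively summed series
  where the quantity is a delivery.

All integrals match brute-force cell loops to 1e-12 relative (tested).

## 6. Synthetic generators

All generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`.

**Seal archive.** Defaults encode the study conditions of the archived
record: n = 72 animals, two-year GLG windows starting uniformly over
1951–2011 (the pooled 1951–2012 coverage; the record does not constrain the
per-year design), ages uniform on 5–12, baseline 11.7 ‰ at the earliest
window midpoint, slope −0.036 ‰ yr⁻¹. Scatter has three Gaussian
components: between-animal (`noise_sd`, default 0.66 ‰), within-sample
replicate (0.45 ‰, which makes occasional duplicate disagreements >1 ‰ and
so exercises the triplication rule), and a per-batch standard drift (0.15 ‰)
shared by sample and standard and removed exactly by the correction. The
default per-record standard deviation, √(0.66² + 0.45²/2) ≈ 0.73 ‰, was
derived once from the design: with midpoints uniform over 1951.5–2011.5
(var ≈ 310 yr²) and slope 0.036 ‰ yr⁻¹, an R² of 43 % requires residual σ ≈
0.73 ‰. With all noise zero the downstream fit recovers the slope to
machine precision.

**Section series.** Noiseless depth×latitude fields per year with an AW core
of n(t) = n₀ + round(n₀·area_trend·t) cells and linear velocity/nitrate/δ
trends; ambient water fails the AW test. The realised transport, its
volume-normalised series and their OLS trends (via an independent
`numpy.polyfit`) are returned as ground truth, making the pure-velocity and
pure-volume decomposition cases exact by construction.

**Regional cubes.** δ¹⁵N_POM cubes with a prescribed per-horizontal-cell
decadal trend map (plus optional iid noise), stationary nitrate, and
volumetric NPP confined to the upper 10 levels; layer thicknesses 10 m
(upper 100 m) then 50 m.

**Telemetry.** Fixes drawn from a Gaussian mixture in the local equal-area
plane about a Barents-Sea centre (default 35°E, 74°N), distributed
round-robin over animals; the mixture density, its kernel-smoothed
counterpart and a sampler for either are retained for oracle tests.

**What the generators do not emulate:** chromatography and instrument peak
behaviour (only the numerical correction is in scope), spatial covariance
and autocorrelation of real ocean fields (cells are independent given their
trends), Argos location error and movement autocorrelation in telemetry, and
any coupling between the seal record and the ocean fields. Passing tests
therefore demonstrate correctness of the inference machinery under the
stated statistical conditions, not the realism of those conditions.

## 7. Problem sizes and determinism

The test suite and acceptance script use the sizes the analyses are designed
around: 72-seal archives (500 replicates for confidence-interval coverage),
2000 telemetry fixes on a 25 km grid, 50-year sections, and 170-year paired
box-model runs. Every stochastic step takes an explicit seed; identical
seeds give byte-identical tables and hash-stable pipeline manifests. NetCDF
is written through xarray's scipy backend (classic NetCDF-3); regions are
GeoJSON; tables are UTF-8 CSV.

## 8. Known limitations

* The box model has no sea ice, no iron/silicate/carbon co-limitation, no
  nitrogen fixation, benthic denitrification or river/erosion inputs; it is
  an attribution instrument for the deposition-vs-utilisation competition,
  not a Barents Sea simulator. Quantitative GCM trend magnitudes are out of
  scope by design; the paired experiment is assessed on sign/ordering
  structure and the calibrated ~5 % nitrate attribution.
* Linear-in-δ mixing misstates δ by up to ~0.01 ‰ at the extremes of the
  ±10 ‰ working range.
* The UD contour is a union of grid cells (area quantised to the 25 km
  grid); the 10 % area tolerance absorbs this comfortably at the default
  resolution.
* OLS trends assume independent annual errors; with autocorrelated fields
  the standard errors (not the slopes) would be optimistic.
* The deposition anchors at 2000/2030 and the two regional scalings are
  demonstration values, clearly surfaced in configuration, and nothing
  downstream of the forcing module depends on their particular magnitudes
  except the attribution percentages themselves.
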