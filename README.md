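# isoscape

Multi-decadal nitrogen-isotope baseline change in the Barents Sea, from seal
teeth to ocean drivers.

## The scientific problem

The base of the Barents Sea food web is changing under three simultaneous
anthropogenic pressures: increasing inflow of Atlantic Water (with a growing
share of isotopically light subtropical-origin nitrate), atmospheric
deposition of reactive nitrogen from fossil-fuel burning and fertiliser use
(δ¹⁵N ≈ −4 ‰), and rising local primary production (which enriches both
nitrate and organic matter in ¹⁵N through assimilation fractionation).
Because phenylalanine undergoes minimal isotope fractionation during trophic
transfer, δ¹⁵N of phenylalanine (δ¹⁵N_Phe) in the annual dentine growth layer
groups (GLGs) of harp seal teeth archives the δ¹⁵N of particulate organic
matter (δ¹⁵N_POM) at the food-web base, year by year, far beyond the reach of
direct observation.

This package implements the full desk-scale inference chain linking such a
tooth record to its drivers:

* **seal record** (`isoscape.seal`) — standard-offset correction of replicate
  GC-IRMS measurements (reported = mean(replicates) − (standard_measured −
  standard_known)), replicate-agreement QC (duplicates within 1.0 ‰ pass,
  otherwise triplicate or fail), GLG chronology (an animal caught in year *c*
  at age *a* laid down its 2nd+3rd GLGs in [c−a+1, c−a+2]), and an OLS fit of
  δ¹⁵N_Phe on window midpoint year with residual diagnostics;
* **telemetry** (`isoscape.telemetry`) — bivariate-normal kernel utilization
  distribution of pooled fixes on a local equal-area plane (default bandwidth
  250 km), with the 95 % highest-density isopleth as the habitat mask;
* **forcing** (`isoscape.forcing`) — the historical reactive-nitrogen
  deposition ramp (11 Tg N yr⁻¹ preindustrial, piecewise linear through
  1850/1950/2000/2030 with 60 % of the 1850–2000 increase after 1950) and the
  Atlantic-inflow scenario (transport trend, subpolar/subtropical endmember
  mixing);
* **box model** (`isoscape.boxmodel`) — a two-box nitrogen-isotope model
  (Atlantic source box → Barents surface box) with mass-weighted δ mixing,
  closed-system Rayleigh fractionation during nitrate assimilation
  (δ_POM = δ_supply + ε·f·ln f/(1−f), δ_resid = δ_supply − ε·ln f),
  Vmax-limited Michaelis–Menten uptake, export/remineralisation and
  through-flow flushing, run as a paired with/without-deposition attribution
  experiment;
* **section diagnostics** (`isoscape.sections`) — Atlantic Water masking
  (θ > 2 °C and S > 34.5 psu), volume transport and its decomposition into
  velocity-driven vs water-mass-volume-driven trends, nitrate flux, masked
  property means, upper-100 m regional means, vertically integrated NPP,
  per-cell decadal trend maps and paired-run attribution percentages;
* **synthetic data** (`isoscape.synthetic`) — seeded generators for every
  input, with ground truth retained, so the whole chain is testable offline.

## Worked example

```python
from isoscape import SealTrendModel, SealTruth, gen_seal_dataset
from isoscape.boxmodel import demo_model

table, truth = gen_seal_dataset(SealTruth(seed=0))   # 72 seals, 1951-2012
fit = SealTrendModel.from_measurements(table).fit()
print(fit.summary())
```

```
delta15N_Phe linear trend (OLS on GLG midpoint year)
  n              : 72
  slope          : -0.0341 permil/yr (-0.341 permil/decade, se 0.052)
  intercept      : 77.989 permil
  R-squared      : 0.383 (38.3%)
  F-statistic    : 43.4 on 1 and 70 df
  p-value        : 6.93e-09
```

The synthetic archive was generated with a true decline of −0.36 ‰ decade⁻¹;
the fitted −0.341 ± 0.052 ‰ decade⁻¹ recovers it within one standard error,
and the fit explains ~38 % of the variance (the generator's scatter is sized
for ~43 %; single archives spread around that).

```python
print(demo_model().paired().summary().round(3).to_string())
```

```
                                       with deposition  without deposition
delta15N inflow trend (permil/decade)           -0.084              -0.029
delta15N POM trend (permil/decade)              -0.050               0.036
NPP trend (g C m-2 decade-1)                     1.407               1.370
cumulative nitrate attribution (%)               4.890               0.000
cumulative NPP attribution (%)                   1.477               0.000
```

Reading the attribution table: the inflow endmember δ¹⁵N_NO3 declines in both
runs (subtropical-water mixing) but almost three times faster once the
deposition ramp acts on the Atlantic source; δ¹⁵N_POM *rises* without
deposition (increasing utilisation pulls the Rayleigh product toward the
supply) but *falls* with it; primary production rises in both runs, and
deposition delivers ~4.9 % extra cumulative nitrate over 1970–2019, amplifying
NPP by ~1.5 %.

A command-line interface wraps the stages:

```sh
isoscape demo --seed 1 --out demo_out      # all-synthetic end-to-end run
isoscape seal-trend --measurements m.csv --out out/
isoscape ud --fixes fixes.csv --bandwidth-km 250 --isopleth 0.95 --out out/
isoscape forcing --from 1850 --to 2019 --out forcing.csv
isoscape boxmodel --paired --out out/
isoscape section --input section.nc --out out/
```

## Documentation

`docs/methods.md` describes the model equations, the parameter defaults and
their rationale, what the synthetic generators do and do not emulate, and the
known limitations.
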