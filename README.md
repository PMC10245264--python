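# lwlr-attrib

Attribution of monthly NDVI dynamics to climate change and anthropogenic
activity with a locally weighted, time-varying-coefficient regression.

## The problem

Vegetation greenness (NDVI) responds to temperature, precipitation and
human pressure, but the response is not stationary: coefficients that
link climate to greenness drift with season, management and land-cover
change, and greenness may lead or lag its meteorological forcing.  A
single global regression therefore misattributes variance, and
residual-trend methods (RESTREND) inherit that misspecification.  This
package estimates, per grid cell, the model

```
N(t) = β0(t) + β1(t) T(t) + β2(t) T²(t) + β3(t) P(t) + β4(t) P²(t) + ε(t)
```

where `N`, `T`, `P` are aligned monthly NDVI, temperature (°C) and
precipitation (mm/month) series of length `M`.  The coefficients are
re-estimated at every focal month by weighted least squares under an
**asymmetric dual-bandwidth Gaussian kernel**

```
W(j, t) = exp(−½((j−t)/h1)²)  for j < t,
          exp(−½((j−t)/h2)²)  for j ≥ t,
```

so past and future months decay at different rates; the ratio
`Rh = h2/h1` encodes lead–lag structure between greenness and climate.
`(h1, h2)` are chosen per cell by exhaustive leave-one-out
cross-validation.  The time-varying intercept `β0(t)` is read as the
non-climatic (anthropogenic) component.

From a fitted cell the package derives:

* **PNC / APNC** — the predicted nonlinear contributions
  `f̂(t) = β̂1T + β̂2T²` (temperature), `ĝ(t) = β̂3P + β̂4P²`
  (precipitation) and `β̂0(t)` (anthropogenic), and their time means
  `f̄, ḡ, β̄0`, plus the anthropogenic share
  `R_ac = β̄0/(f̄+ḡ+β̄0)`.
* **Average changing trends** — the climate contribution `f̂+ĝ` is
  STL-detrended, the trend curve is fitted by a cubic in `t`, and
  `α = ⟨d/dt⟩` of that cubic is its average trend; `α0` is the same
  statistic for `β̂0(t)`.  The relative contribution ratios are
  `Ra = α0/(α0+α)` and `Rc = 1−Ra`.
* **Diagnostics** — kernel-weighted variance inflation factors, the
  Durbin–Watson statistic with Cochrane–Orcutt AR(1) correction when it
  leaves [1.70, 2.30], and a residual-normality screen ΔP (max distance
  between the residual KDE and a fitted normal density) against a
  Monte-Carlo calibrated threshold τ = 0.04.

A synthetic-data module generates grid cells with seasonal, trending,
AR(1) climate and known time-varying coefficients, so every estimator is
tested against ground truth.

## Worked example

```python
from lwlr_attrib import make_grid, run_grid, RunConfig

cells, truths = make_grid(10, "anthropogenic-dominant", seed=42)
table, summary = run_grid(cells, RunConfig())
row = table.iloc[0]
print(f"h=({row.h1:.0f},{row.h2:.0f})  Rlg={row.rlg:.3f}  "
      f"Ra={row.ra:.2f}  Rc={row.rc:.2f}  alpha0={row.alpha0:.2e}")
print(f"mean Ra over grid: {summary['mean_ra']:.3f}")
```

prints

```
h=(18,18)  Rlg=1.177  Ra=0.94  Rc=0.06  alpha0=4.32e-04
mean Ra over grid: 1.005
```

The cells were generated with a rising anthropogenic intercept
(slope 5×10⁻⁴ NDVI/month) and trendless climate: the pipeline recovers
`alpha0` near the generating slope, `Ra > 0.5` (anthropogenic activity
dominates the NDVI trend; a grid-mean slightly above 1 means some cells'
small estimated climate trends were negative), and `Rlg > 1` (the local
model explains more variance than the global OLS baseline).

Command-line equivalents:

```sh
lwlr-sim --n-cells 10 --scenario anthropogenic-dominant --seed 42 \
         --out grid.csv --truth-out truth.json
lwlr-attrib run --input grid.csv --out results/
lwlr-attrib calibrate-tau --n 10000 --length 240 --seed 1
```

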