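# Methods

## Model and estimator

Each grid cell carries aligned monthly series of NDVI `N(t)`,
temperature `T(t)` (°C) and precipitation `P(t)` (mm/month),
`t = 1..M`, `M ≥ 36`.  The working model is additive and quadratic in
each climate variable with time-varying coefficients:

```
N(t) = β0(t) + β1(t)T(t) + β2(t)T²(t) + β3(t)P(t) + β4(t)P²(t) + ε(t).
```

At each focal month `t` the coefficient vector minimises the
kernel-weighted sum of squares over all months `j`, with the asymmetric
Gaussian weight `W(j,t)` using bandwidth `h1` for `j < t` and `h2` for
`j ≥ t`.  The solution is the weighted normal-equations estimator
`β̂(t) = (XᵀW(t)X)⁻¹XᵀW(t)N`, batch-solved for all `t` at once;
numerically singular moment matrices (condition number beyond 1/eps)
fall back to the pseudo-inverse with a per-month flag — no ridge
penalty is added silently.  Design columns are used raw, without
centering or standardisation; conditioning is the solver's job and the
singularity flag records where it fails.

The constant-coefficient OLS fit on the same design is the baseline.
Both fits report the explained-variance statistic
`R² = Σ[N̂−N̄]²/Σ[N−N̄]²`.  For the local model the fitted values and
residuals do not partition the total sum of squares, so this form is
**not** equal to `1 − SSE/SST` and `Rl²` may exceed 1 for aggressive
bandwidths; the form is kept deliberately, and the ratio
`Rlg = Rl²/Rg²` compares local against global explanatory ability.

Bandwidths are constrained to `h ≥ 1` month so the kernel keeps a few
effective observations per local system (five unknowns) near the series
ends.  All `M` weights are always used (no truncation; `M` is a few
hundred).  Months within `max(h1,h2)` of either end carry a
`boundary_flag`: the truncated kernel inflates end-point variance, and
the flag is exposed rather than padding or reflecting the series.

## Bandwidth selection

`(h1, h2)` are selected per cell by exhaustive leave-one-out
cross-validation: the weight of the focal month is zeroed, the local
model refitted, and `CV(h) = Σ_t (N(t) − N̂₋t(t))²` minimised over the
Cartesian grid `h1, h2 ∈ {1, 2, 3, 4, 6, 9, 12, 18, 24, 36, 48}`
months (the grid is a package default, chosen to span sub-seasonal to
multi-annual smoothing at roughly geometric spacing).  The minimised
quantity is the printed sum of squares; the order-equivalent RMSE is
reported alongside.  Boundary months are included in the CV sum.  Exact
ties break toward smaller `h1+h2`, then `h2/h1` closest to 1, then
lexicographic order, so selection is deterministic.

Two behavioural facts, established by the test suite, are worth
knowing:

* With constant generating coefficients the CV selects among the
  largest candidates, and rapidly varying coefficients pull it down —
  the selector adapts flexibility in the right direction.
* Under serially correlated noise, leave-one-out CV selects bandwidths
  that are too small, absorbing the autocorrelation into the
  coefficient paths (the classic failure of LOO under dependence).
  The pipeline's Durbin–Watson stage is the guard: when the chosen
  bandwidths do leave autocorrelated residuals, Cochrane–Orcutt
  correction engages.

### Lead–lag convention

`Rh = h2/h1 > 1` is reported with the convention that NDVI temporally
lags the meteorological forcing.  Empirically, in paired experiments
where NDVI is generated from climate delayed by two months (with a
slowly varying temperature coefficient so that window shape matters),
the selected `Rh` shifts upward relative to the matched no-lag cell in
the majority of replicates — consistent with that reading.  With
constant generating coefficients the unpaired side preference is too
weak to detect: the constant model refits well under any window, so
only the paired contrast is informative.

## Diagnostics

* **Weighted VIF.**  For each focal month and each predictor
  `x_i ∈ {T, T², P, P²}`, `VIF_i(t) = 1/(1−R_i²(t))` from the
  `W(·,t)`-weighted regression of `x_i` on the remaining predictors
  plus intercept.  With all weights equal it reduces to the textbook
  VIF.  Values above 4 raise a flag.  Note that `T` with `T²` (and `P`
  with `P²`) are intrinsically collinear when the series' range is
  small relative to its mean, so large VIFs are expected on some
  synthetic cells; the flag is informational, not a gate.
* **Durbin–Watson.**  `Σ(e_t−e_{t−1})²/Σe_t²` on the residual series
  of the local fit, one statistic per cell; acceptance band
  [1.70, 2.30].  A per-month kernel-weighted variant is not attempted
  because no printed formula pins it down; the uniform-weight limit is
  the verifiable contract.
* **Cochrane–Orcutt.**  When DW leaves the band, iterate: estimate
  `ρ̂` as the lag-1 autocorrelation of the original-scale residuals,
  quasi-difference the response and every design column
  (`z*(t) = z(t) − ρ̂z(t−1)`, first observation dropped, no
  Prais–Winsten correction), refit, and stop when `ρ̂` moves less than
  `tol` (default 1e-3) or after `max_iter` (default 20, warning on
  non-convergence).  Because the intercept column is transformed with
  the rest, the returned trajectories stay on the original coefficient
  scale.  Local smoothing absorbs part of the autocorrelation, so `ρ̂`
  is mildly biased toward zero; at bandwidth 12 and generating
  `ρ = 0.6` the 50-seed mean lands within 0.1 of truth.
* **Residual normality (ΔP).**  Residuals are standardised by their
  sample mean and standard deviation; a Gaussian KDE with Silverman's
  rule-of-thumb bandwidth (scipy's `bw_method="silverman"`) and the
  standard normal density are evaluated on 512 points over ±5
  standardised units, and ΔP is the maximum absolute pointwise
  difference.  Standardising makes ΔP exactly invariant under affine
  transformations of the residuals, so a single threshold calibrated on
  N(0,1) samples applies to residuals of any magnitude — this is the
  reason the comparison is done on the standardised scale rather than
  on the raw residual density (whose height scales as 1/σ).
* **τ calibration.**  τ is the mean ΔP over 10,000 standard-normal
  datasets, rounded to two decimals; the per-dataset length defaults to
  240 (the 20-year monthly record the method targets; ΔP shrinks with
  length, so τ is tied to the record length).  With these settings the
  calibration yields τ = 0.04 (mean ΔP ≈ 0.042, sd ≈ 0.014).  The
  screen `ΔP < τ` is strict at the boundary.  Because τ sits at the
  null mean, genuinely normal residuals pass roughly half the time —
  the screen is a tight plausibility filter, not a size-α test; the
  empirical pass rate is reported rather than a nominal level.

## Attribution

The fitted cell splits additively into the temperature PNC
`f̂ = β̂1T + β̂2T²`, precipitation PNC `ĝ = β̂3P + β̂4P²` and
anthropogenic PNC `β̂0`, summing exactly to the fitted NDVI.  Their
time means are the APNC `f̄, ḡ, β̄0`, and
`R_ac = β̄0/(f̄+ḡ+β̄0)` is the anthropogenic share (undefined below a
1e-12 denominator tolerance; reported with bins ≤0.5, 0.51–0.75,
0.76–1, >1).

Trends: the climate PNC `f̂+ĝ` is STL-decomposed (period 12, robust
mode, seasonal window 13 — STL is named without parameters in the
method's sources, so these are package defaults) and its trend
component fitted by a cubic in `t`; `α` is the mean of the cubic's
first derivative over `t = 1..M` (closed form
`(1/M)Σ(3c₃t²+2c₂t+c₁)`).  `β̂0(t)` is fed to the cubic directly — it
carries no seasonal cycle of its own, so no STL — giving `α0`;
likewise `α1`, `α3` for the `β̂1`, `β̂3` trajectories.  The cubic is
solved on a [0,1]-rescaled time axis for conditioning and mapped back.
The cubic-fit convention is used for all four trend statistics (rather
than numerically differentiating the trend curve itself); a
finite-difference alternative is exposed for the ingredient terms.

`Ra = α0/(α0+α)`, `Rc = 1−Ra`, flagged undefined when
`|α0+α| < 1e-12`.  Negative `Ra` is reported as anthropogenic
degradation against a promoting climate (and conversely).  A
categorical driver class comes from the sign quadrant of `(α0, α)` with
`|·| < 5×10⁻⁶ /month` treated as insignificant.

The first-order ingredient decomposition of `α` drops the quadratic
climate terms:

```
dFĜ/dt ≈ T·dβ̂1/dt + β̂1·dT/dt + P·dβ̂3/dt + β̂3·dP/dt,
```

with coefficient derivatives from the cubic fits and climate
derivatives as OLS linear slopes of the raw series (per-month central
differences available by option).  The temperature vs precipitation
mean shares label the dominant factor, with a 60/40 split required for
a single-factor label, else "combination" (the labelling rule is an
implementation choice; no printed formula exists for it).

NDVI greening classes use the OLS slope of the STL trend of NDVI:
degraded (< −2×10⁻⁵/month), non-significant (within ±2×10⁻⁵), promoted
(> 2×10⁻⁵), strongly promoted (> 2×10⁻⁴).

### Identities and invariances (all test-enforced)

* `f̂+ĝ+β̂0 = N̂` per month; means close additively.
* `Ra + Rc = 1` whenever defined.
* Rescaling NDVI by `c` scales `f̄, ḡ, β̄0, α, α0` by `c` and leaves
  `Ra, Rc, R_ac` unchanged.
* ΔP is affine-invariant; DW is reversal-invariant.

## Pipeline

Per-cell stage order: no-vegetation mask (mean NDVI ≤ 0.15, boundary
inclusive) → bandwidth CV → weighted VIF → fit → DW → Cochrane–Orcutt
if DW out of band → ΔP screen on the final residuals → attribution →
NDVI slope class.  The order is a package decision (the checks
themselves do not prescribe one); re-selection of bandwidths after
correction is not performed.  After a Cochrane–Orcutt pass, attribution
uses the corrected coefficient trajectories with the original climate
series from month 2 onward; the corrected fit's own fitted values live
on the quasi-differenced scale and are used only for residual
diagnostics.  Cells fail in isolation with the failing stage recorded;
cells with any missing month are rejected at ingest rather than
imputed.  Batch runs are deterministic given input and config, and
byte-identical on rerun.

## Synthetic data

The generator emulates what the method assumes: climate as
mean + seasonal cosine + linear trend + AR(1) noise (precipitation
truncated at 0 — simpler than a log-normal model, at the cost of mildly
distorting the AR structure near the floor), coefficients as constant /
linear / cubic / sinusoidal functions of `t`, NDVI assembled through
the quadratic model with optional AR(1) noise and an optional lag that
shifts the climate inputs.  Default magnitudes (`β1 ~ 10⁻²`,
`β2 ~ 10⁻⁴`, `β3 ~ 10⁻³`, `β4 ~ 10⁻⁶`, intercept ≈ 0.25, NDVI noise
σ = 0.01) keep NDVI in a realistic [0, 1]-like range for a temperate
monsoon setting.  Named scenarios (climate-dominant,
anthropogenic-dominant, degrading, lagged, no-vegetation, time-varying)
fix the generating structure for recovery experiments; generation is
bit-identical given parameters and seed.

What the generator does **not** emulate: spatial correlation between
cells, heteroscedastic or non-Gaussian NDVI noise, observation gaps,
satellite compositing artefacts, and realistic regional climatology.
Passing recovery tests therefore demonstrate estimator correctness
under the model's own assumptions, not robustness to everything real
remote-sensing data can do.

## Problem sizes

Tests and the calibration script run at the method's native scale where
that is cheap (M = 240 months throughout; 10,000 calibration datasets
in the script, 2,000 in the test suite's smoke check; 25–50 seeds or
cells per stochastic experiment), because the batched linear algebra
makes a full cross-validated cell fit a sub-second operation.

## Known limitations

* The "weighted" Durbin–Watson and VIF exist in the literature in
  several forms; the uniform-weight limits are the only contracts
  verified here.
* `Rl²` above 1 is possible by construction (explained-variance form);
  interpret `Rlg` comparatively, not as a variance fraction.
* τ depends on the calibration series length, which is a package
  default (240), not an externally fixed constant.
* Leave-one-out CV under strong serial dependence undersmooths; the
  DW → Cochrane–Orcutt stage mitigates but does not remove this.
* End-point coefficient estimates are flagged, not corrected.
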