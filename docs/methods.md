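# Methods

## The model

The package estimates the association between population-level alcohol
consumption and cause-specific cancer mortality from annual aggregate
series.  The structural equation is a differenced semi-log regression with
time-structured errors:

    Δ ln M_t = α + β ΔWA_t + Σ_i μ_i ΔC_{i,t} + ΔE_t

* **M_t** — cancer mortality rate per 100,000 persons 15+ (one cause, one
  sex/age stratum).  Working on ln M makes β a semi-elasticity — chronic
  disease risk is convex in intake, and a proportional effect per litre is
  the natural aggregate summary: one litre per capita changes mortality by
  (e^β − 1)×100 percent.
* **WA_t** — lag-weighted per-capita consumption, WA_t = Σ_k w_k x_{t−k}
  with w ≥ 0, Σw = 1.  Cancer follows drinking with delays of up to two
  decades, so the raw series cannot enter contemporaneously.
* **C_{i,t}** — controls (tobacco consumption, health expenditure), each
  lag-weighted with its own profile before entering.
* **ΔE_t** — ARMA-structured error.  The dominant error structure on
  differenced log mortality is MA(1), i.e. ARIMA(0,1,1) on the level
  series; other orders ((1,1,1), (1,1,3)) are available per stratum.

First differencing (d = 1 in every model) removes the common stochastic
trends that would otherwise produce spurious regression between integrated
series; the ADF test (constant, no trend, AIC lag selection up to
⌊(n−1)^(1/3)⌋) is provided as the supporting diagnostic.  The package
reports ADF on logs and on first differences and keeps d fixed at 1 rather
than choosing d per stratum, because the modelling chain is built around
the differenced equation.

## Lag identification and weighting

Both series are first-differenced; an AR model (order by AIC, ≤ 5) is
fitted to the differenced exposure and its AR polynomial applied to both
series (pre-whitening), so shared autocorrelation cannot inflate the
cross-correlations.  The CCF is then corr(x_{t−k}, y_t) for k = 0..25
(default cap, bounded by length/3), with the two-sided critical band
±2/√n, n the overlapping years at lag 0.

Published analyses of this design report a single lag length read from the
extreme significant lag of the CCF plot; `select_lag_length` therefore
returns the **largest lag with a significant positive correlation** (0 if
none).  How estimated "cross-correlation lag weights" become a weight
profile is genuinely underdetermined in the literature, so the package
makes the rule explicit and configurable:

* `ccf` (default): w_k ∝ ccf[k] over significant positive lags ≤ L,
  normalised; uniform fallback over 0..L when nothing is significant.
  This uses exactly the estimated lag correlations and always yields a
  proper profile.
* `point`: all weight at the selected lag.
* `geometric`: w_k ∝ decay^k (Koyck), the sensitivity-analysis structure
  favouring recent years.  The decay parameter is not fixed by any
  published value; the default 0.9 keeps non-negligible weight across a
  15–20-year window, and it is exposed in configuration.

Negative lags (mortality leading exposure) are never used in weighting.
Lag profiles identified on total-cancer mortality per sex are applied to
every cancer subtype of that sex — the standard assumption that the delay
does not differ by cancer type — but the profile is an explicit input, so
the assumption is visible and overridable.

## Estimation and inference

The regression is fitted by exact maximum likelihood in state-space form
on the manually differenced scale — `ARIMA(Δln M, exog=ΔWA…, order=(p,0,q),
trend="c")` — which is identical to an ARIMA(p,1,q)-with-drift fit on
levels and keeps the fitted equation exactly the structural one.  Starting
values are deterministic (Hannan–Rissanen), with a derivative-free Powell
refinement from the stalled point if L-BFGS reports non-convergence; the
same input therefore always yields the same estimates.  A condition-number
guard (>1e8 on the standardised design) rejects near-collinear exposure
sets rather than returning unstable coefficients.

Inference is two-sided Wald with normal critical values (95% CIs).
Residuals are checked with the Box-Ljung portmanteau at 10 lags, degrees of
freedom reduced by the number of ARMA parameters.  R² is reported on the
differenced scale (1 − SSE/SST of Δln M) — the only scale on which the
model is linear — and is the quantity compared between main and
sensitivity runs.

## Attributable fractions

The aggregate-data AAF is AACP × (e^β − 1)×100, where AACP is the average
per-capita consumption over the observation window.  The intermediate form
(AACP·E)/AM with E = (e^β − 1)×100·AM is algebraically identical for any
average mortality AM > 0 (tested as an invariant).  The whole-population
AACP splits by sex as AACP_male = AACP_total·2·share with share = 0.675
(survey-based male share of total consumption) under equal-sized sex
populations; an optional males-per-female ratio generalises the factor 2.
Published worked examples multiply the *rounded* one-decimal effect by the
sex-specific AACP, so report-precision arithmetic follows that convention.
AAFs are computed only for significant (p < 0.05), positive alcohol
coefficients, and clamped to [0, 100] with a warning — the formula is a
linear approximation valid over small consumption changes.  The
observation window for AACP is configuration, not a constant.

## Synthetic data

`synthetic_data` runs the structural equation forwards: a deterministic
exposure trend plus seeded noise → lag-weighted index under a known
profile → Δln M assembled from β, μ and an MA(1) disturbance → integrated
from a baseline log rate and exponentiated.  Defaults define the study
conditions: 109 annual observations (1910–2018), β = 0.035/L,
μ_tobacco = 0.2/kg, μ_health = −0.02 (expenditure is protective, so
omitting it biases the alcohol effect), geometric-0.9 profile over lags
0..20, θ = 0.3, innovation sd 0.005 on the Δlog scale, baseline 20 per
100,000.

The exposure shapes echo 20th-century consumption histories and are
deliberately distinct: alcohol ~4.8 L rising from mid-century to ~11 L in
the mid-1970s then declining to ~8 L; tobacco peaking earlier with a
steeper fall; health expenditure growing monotonically (recorded only from
25 years into the study period, mimicking shorter expenditure statistics,
though it affects mortality throughout).  Distinct trends are an
identifiability requirement as much as realism: identical shapes would
make the lag-weighted differenced regressors nearly collinear.  A
`random-walk` exposure (reflected, step sd 0.3 L) provides the
innovation-rich input that lag identification needs, and `flat` the
degenerate control.  Lung-like outcomes are generated with zero alcohol
effect and the full tobacco effect, giving the negative control.

What the generator does **not** emulate: measurement error in consumption
(unrecorded alcohol), age-structure drift under direct standardisation,
abrupt interventions (wars, rationing), cohort effects, or any feedback
from mortality to consumption.  Passing tests therefore show the estimator
is correct *under its own assumptions* — unbiased, correctly covered,
calibrated, specific — not that those assumptions hold in any historical
record.

## Problem sizes and numerical choices

Monte-Carlo checks use 200 replicates for coefficient recovery (bias and
CI coverage), 100 for lag recovery and negative-control specificity, 500
for Ljung-Box size, and 100 for ADF behaviour — sizes at which the
binomial noise on a 90% pass criterion is a few percent.  Ties in
`select_lag_length` cannot occur (strict inequality against the band);
equal CCF values at different lags both receive weight.  Internal gaps in
input series are a hard error, never interpolated, because silent
interpolation corrupts differencing.  Weight profiles are validated to
Σw = 1 within 1e-9; the log transform refuses non-positive rates naming
the offending year.

## Known limitations

* Alcohol×tobacco interaction cannot be estimated in this aggregate
  time-series design; the model is additive on the Δlog scale.
* The CCF weighting rule is one defensible choice among several (raw vs
  normalised vs point mass); results can be sensitive to it, which is why
  all three are selectable and the geometric profile ships as a
  sensitivity variant.
* AAF is a linear approximation in consumption; large extrapolations are
  clamped, not trusted.
* No automatic ARIMA order search: orders are configuration, matching how
  such studies report fixed per-stratum orders.
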