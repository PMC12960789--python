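# alcolag

Aggregate time-series analysis of population alcohol consumption and
cause-specific cancer mortality.

`alcolag` is for epidemiologists who work with *aggregate* (population-level)
annual data: per-capita alcohol consumption (litres of pure ethanol, persons
15+), per-capita tobacco consumption, health expenditure, and cause-specific
cancer mortality rates per 100,000.  It implements the full modelling chain
used to ask "if population drinking fell by one litre per head, how much
cancer mortality would follow it down, and after how long?":

1. **Lag identification** — pre-whitened cross-correlation between the
   differenced exposure and outcome series, with the ±2/√n critical band,
   to find how many years separate a change in drinking from its effect on
   mortality (typically around 20 years).
2. **Lag-weighted exposure** — a weighted index
   WA_t = Σ_k w_k·x_{t−k} with non-negative weights summing to one, built
   either from the significant positive cross-correlations or from a
   geometric (Koyck) profile that favours recent years.
3. **Differenced semi-log ARIMA regression** —

       Δ ln M_t = α + β ΔWA_t + Σ_i μ_i ΔC_{i,t} + ΔE_t

   with ARMA-structured errors (dominantly MA(1), i.e. ARIMA(0,1,1) on log
   mortality), fitted by exact maximum likelihood.  β is a semi-elasticity:
   one litre per capita changes the mortality rate by (e^β − 1)×100 percent.
4. **Attributable fractions** — the aggregate-data AAF
   = AACP × (e^β − 1)×100, with the whole-population average consumption
   split between the sexes (males ≈ 67.5% of all alcohol consumed).

Because the historical registry series behind such studies cannot be
redistributed, the package ships a synthetic-data generator that runs the
same structural model *forwards* with known coefficients and lag profiles,
so every stage — lag recovery, coefficient recovery, CI coverage,
diagnostic calibration, negative-control specificity — is testable against
ground truth.

## Worked example

Simulate a century-long study (true per-litre effect β = 0.035 on UADT
cancer mortality, 20-year lag profile, MA(1) noise), then fit and attribute:

```sh
$ alcolag simulate --seed 3 --out study.csv
wrote study.csv and ground truth sidecar

$ alcolag fit study.csv --outcome uadt --sex male
ARIMA(0,1,1)  n=88  R2=0.816  Q10 p=0.246
beta = 0.0383  95% CI (0.0222, 0.0544)  p=0.0000
per-litre effect: 3.9% (2.2, 5.6)

$ alcolag aaf --aacp-total 9.35 --effect 3.6 --sex male
male AACP = 12.6 L; AAF = 45.4%
```

Reading the output: the fitted β = 0.038 sits well inside its CI of the
generating value 0.035; the per-litre effect says each litre of per-capita
consumption moves UADT mortality by about 3.9% (the transform of β); the
Ljung-Box Q(10) p-value of 0.25 shows no leftover residual autocorrelation.
The last line is the attribution arithmetic: a 9.35 L whole-population
average with a 67.5% male share is 12.6 L per male, and at 3.6% per litre
that makes 45.4% of male UADT cancer deaths alcohol-attributable.

The same flow is available as a library (`read_dataset`, `prewhiten`,
`cross_correlate`, `ccf_weights`, `apply_weights`, `fit_arimax`,
`effect_transform`, `compute_aaf`) and as a one-shot pipeline
(`run_main_analysis`, `run_sensitivity`) driven by a YAML config — see
`alcolag run --help`.  Sensitivity variants re-run the identical flow with
one element changed: geometric 15/20-year lags, no health-expenditure
control, or lung-cancer outcomes as a negative control (lung mortality
should follow tobacco, not alcohol).

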