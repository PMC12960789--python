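"""Differenced semi-log ARIMA regression and the per-litre effect transform.

The structural model is

    Δ ln M_t = α + β ΔWA_t + Σ_i μ_i ΔC_{i,t} + ΔE_t,

where M_t is a cancer mortality rate per 100,000, WA_t the lag-weighted
per-capita alcohol consumption (litres of pure ethanol, persons 15+), the
C_{i,t} are lag-weighted controls (tobacco consumption, health
expenditure), and the differenced error ΔE_t follows an ARMA(p, q) process
— in the main models an MA(1), i.e. ARIMA order (0,1,1) on the level
series.  Because the outcome is a log rate, β is a semi-elasticity: one
extra litre of per-capita consumption multiplies the mortality rate by
e^β, i.e. changes it by (e^β − 1)×100 percent.

Estimation is exact maximum likelihood via the state-space form, fitted on
the manually differenced scale with a constant (the drift α), which is
identical to an ARIMA(p,1,q)-with-drift fit on the level series and keeps
the fitted equation exactly the structural one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tsa.arima.model import ARIMA

from .preprocess import difference
from .timeseries_io import MIN_FIT_OVERLAP, AnnualSeries, align_many

__all__ = ["ArimaSpec", "ArimaxFit", "EffectEstimate", "fit_arimax",
           "effect_transform", "ljung_box_q10"]

#: condition-number ceiling for the standardised differenced design matrix
_COND_LIMIT = 1e8


@dataclass(frozen=True)
class ArimaSpec:
    """ARIMA order (p, d, q); all study models use d = 1."""

    p: int = 0
    d: int = 1
    q: int = 1

    def __post_init__(self) -> None:
        if self.p < 0 or self.q < 0 or self.d < 0:
            raise ValueError("ARIMA orders must be non-negative")

    def __str__(self) -> str:
        return f"{self.p},{self.d},{self.q}"


@dataclass(frozen=True)
class ArimaxFit:
    """One fitted model: coefficients, Wald inference, diagnostics.

    ``beta_hat`` is the coefficient of the primary (alcohol) exposure;
    ``covar_coefs`` holds the μ of every control.  Keys of ``se``/``ci95``/
    ``p_values`` are ``"alpha"``, ``"beta"`` and the control labels.
    """

    spec: ArimaSpec
    exposure_label: str
    alpha_hat: float
    beta_hat: float
    covar_coefs: dict[str, float]
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    q10_stat: float
    q10_p: float
    n_obs: int
    r_squared: float
    loglike: float
    residuals: np.ndarray = field(repr=False)

    def coefficient(self, name: str) -> float:
        if name in ("beta", self.exposure_label):
            return self.beta_hat
        if name == "alpha":
            return self.alpha_hat
        if name in self.covar_coefs:
            return self.covar_coefs[name]
        raise KeyError(f"unknown coefficient {name!r}")

    def _key(self, name: str) -> str:
        if name in ("beta", self.exposure_label):
            return "beta"
        if name == "alpha" or name in self.covar_coefs:
            return name
        raise KeyError(f"unknown coefficient {name!r}")


@dataclass(frozen=True)
class EffectEstimate:
    """Percent change in the mortality rate per one-litre consumption change.

    The point estimate and both confidence limits are the elementwise
    transform (e^β − 1)×100 of the regression coefficient and its CI.
    """

    percent_per_litre: float
    ci95_percent: tuple[float, float]
    p_value: float

    @classmethod
    def from_beta(cls, beta: float, ci95: tuple[float, float] = (np.nan, np.nan),
                  p_value: float = np.nan) -> "EffectEstimate":
        lo, hi = ci95
        return cls(percent_per_litre=float(np.expm1(beta) * 100.0),
                   ci95_percent=(float(np.expm1(lo) * 100.0), float(np.expm1(hi) * 100.0)),
                   p_value=float(p_value))

    @classmethod
    def from_percent(cls, percent: float, ci95_percent: tuple[float, float] = (np.nan, np.nan),
                     p_value: float = np.nan) -> "EffectEstimate":
        """Wrap an already-transformed percentage (e.g. a published 3.6%/L)."""
        return cls(percent_per_litre=float(percent),
                   ci95_percent=(float(ci95_percent[0]), float(ci95_percent[1])),
                   p_value=float(p_value))


def fit_arimax(outcome_log: AnnualSeries, exposures: Sequence[AnnualSeries],
               spec: ArimaSpec = ArimaSpec()) -> ArimaxFit:
    """Fit the differenced semi-log regression with ARMA errors.

    Parameters
    ----------
    outcome_log:
        Log mortality series (already log-transformed).
    exposures:
        Lag-weighted exposure series; the first is the primary (alcohol)
        exposure whose coefficient is reported as β, the rest are controls.
    spec:
        ARIMA order; ``d`` differencings are applied to outcome and all
        exposures before the ML fit (all study models use d = 1).

    Returns an :class:`ArimaxFit` with Wald 95% CIs (normal critical
    values), the Box-Ljung Q(10) portmanteau on the residuals (degrees of
    freedom reduced by p+q), and R² of the differenced regression.
    """
    if not exposures:
        raise ValueError("fit_arimax requires at least one exposure series")
    aligned = align_many([outcome_log, *exposures])
    if len(aligned[0]) < max(MIN_FIT_OVERLAP - 5, spec.d + spec.p + spec.q + 5):
        raise ValueError(
            f"only {len(aligned[0])} overlapping years; too short to fit reliably"
        )
    diffed = [difference(s, spec.d) if spec.d else s for s in aligned]
    idx = pd.period_range(start=str(diffed[0].start_year), periods=len(diffed[0]),
                          freq="Y")
    y = pd.Series(diffed[0].values, index=idx)
    labels = [s.label for s in aligned[1:]]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate exposure labels: {labels}")
    X = pd.DataFrame({lab: d.values for lab, d in zip(labels, diffed[1:])},
                     index=idx)

    # collinearity guard on the standardised design
    Xs = (X - X.mean()) / X.std(ddof=0)
    if np.ptp(X.to_numpy(), axis=0).min() == 0:
        raise ValueError("an exposure is constant after differencing")
    cond = np.linalg.cond(np.column_stack([np.ones(len(Xs)), Xs.to_numpy()]))
    if cond > _COND_LIMIT:
        raise ValueError(f"exposure design is near-collinear (condition number {cond:.3g})")

    model = ARIMA(y, exog=X, order=(spec.p, 0, spec.q), trend="c",
                  enforce_stationarity=True, enforce_invertibility=True)
    import warnings as _warnings
    from statsmodels.tools.sm_exceptions import ConvergenceWarning
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            res = model.fit(method_kwargs={"disp": False, "maxiter": 200})
            if not res.mle_retvals.get("converged", True):
                # deterministic fallback: refine from the stalled point with
                # a derivative-free pass
                res = model.fit(start_params=res.params,
                                method_kwargs={"disp": False, "maxiter": 500,
                                               "method": "powell"})
    except Exception as exc:  # pragma: no cover - optimiser failure path
        raise RuntimeError(f"ARIMAX estimation failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(
            f"ARIMAX optimiser did not converge: {res.mle_retvals.get('message', '')}"
        )

    params = res.params
    conf = res.conf_int(alpha=0.05)
    pvals = res.pvalues
    bse = res.bse

    def _entry(key: str) -> tuple[float, float, tuple[float, float], float]:
        return (float(params[key]), float(bse[key]),
                (float(conf.loc[key, 0]), float(conf.loc[key, 1])),
                float(pvals[key]))

    alpha_hat, alpha_se, alpha_ci, alpha_p = _entry("const")
    beta_hat, beta_se, beta_ci, beta_p = _entry(labels[0])

    covar_coefs: dict[str, float] = {}
    se = {"alpha": alpha_se, "beta": beta_se}
    ci95 = {"alpha": alpha_ci, "beta": beta_ci}
    p_values = {"alpha": alpha_p, "beta": beta_p}
    for lab in labels[1:]:
        c, s_, ci, p = _entry(lab)
        covar_coefs[lab] = c
        se[lab], ci95[lab], p_values[lab] = s_, ci, p

    resid = np.asarray(res.resid, dtype=float)
    q10_stat, q10_p = ljung_box_q10(resid, model_df=spec.p + spec.q)

    sst = float(np.sum((y - y.mean()) ** 2))
    r_squared = float(1.0 - np.sum(resid ** 2) / sst) if sst > 0 else np.nan

    return ArimaxFit(spec=spec, exposure_label=labels[0], alpha_hat=alpha_hat,
                     beta_hat=beta_hat, covar_coefs=covar_coefs, se=se, ci95=ci95,
                     p_values=p_values, q10_stat=q10_stat, q10_p=q10_p,
                     n_obs=int(len(y)), r_squared=r_squared,
                     loglike=float(res.llf), residuals=resid)


def effect_transform(fit: ArimaxFit, coefficient: str = "beta") -> EffectEstimate:
    """Per-litre percent effect (e^β − 1)×100 for a fitted coefficient."""
    key = fit._key(coefficient)
    beta = fit.coefficient(coefficient)
    return EffectEstimate.from_beta(beta, fit.ci95[key], fit.p_values[key])


def ljung_box_q10(residuals: np.ndarray, model_df: int = 0) -> tuple[float, float]:
    """Box-Ljung portmanteau test of the first 10 residual autocorrelations.

    Degrees of freedom are 10 − ``model_df`` where ``model_df`` counts the
    fitted ARMA parameters; requires at least 30 observations.
    """
    r = np.asarray(residuals, dtype=float)
    if r.ndim != 1 or r.size < 30:
        raise ValueError("ljung_box_q10 requires a 1-d series of length >= 30")
    if np.ptp(r) == 0:
        raise ValueError("degenerate (constant) residual series")
    tab = acorr_ljungbox(r, lags=[10], model_df=model_df)
    return float(tab["lb_stat"].iloc[0]), float(tab["lb_pvalue"].iloc[0])
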