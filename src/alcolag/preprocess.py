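"""Pre-model transformations: log, differencing, ADF test, age-standardisation.

The modelling chain works on the natural log of mortality rates and on first
differences, so the regression coefficient of exposure is a proportional
(semi-log) effect and common stochastic trends are removed before any
association is estimated.  The augmented Dickey-Fuller test documents why a
single differencing is applied: annual consumption and mortality series are
integrated of order one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from statsmodels.tsa.stattools import adfuller

from .timeseries_io import AnnualSeries, align_many

__all__ = ["AdfResult", "log_series", "difference", "adf_test", "age_standardise"]


@dataclass(frozen=True)
class AdfResult:
    """Outcome of an augmented Dickey-Fuller unit-root test."""

    statistic: float
    p_value: float
    n_lags_used: int
    stationary_at_05: bool

    def __post_init__(self) -> None:
        assert self.stationary_at_05 == (self.p_value < 0.05)


def log_series(s: AnnualSeries) -> AnnualSeries:
    """Natural log of a strictly positive series.

    Raises ``ValueError`` naming the first offending year if any value is
    not strictly positive (a zero mortality rate cannot be log-transformed).
    """
    bad = np.flatnonzero(s.values <= 0)
    if bad.size:
        raise ValueError(
            f"series {s.label!r}: non-positive value at year {s.start_year + int(bad[0])}; "
            "cannot take log"
        )
    return s.with_values(np.log(s.values), unit=f"log({s.unit})" if s.unit else "log")


def difference(s: AnnualSeries, order: int = 1) -> AnnualSeries:
    """Difference a series ``order`` times; start year advances by ``order``."""
    if order < 1:
        raise ValueError("difference order must be >= 1")
    if len(s) <= order:
        raise ValueError(f"series {s.label!r} too short to difference {order} time(s)")
    return s.with_values(np.diff(s.values, n=order), start_year=s.start_year + order)


def adf_test(s: AnnualSeries, regression: str = "c") -> AdfResult:
    """Augmented Dickey-Fuller unit-root test with AIC lag selection.

    Deterministic term is a constant (no trend) by default; the maximum lag
    follows the usual ⌊(n-1)^(1/3)⌋ rule.  A rejection at the 5% level is
    reported as ``stationary_at_05``.
    """
    if len(s) < 15:
        raise ValueError("adf_test requires at least 15 observations")
    if np.ptp(s.values) == 0:
        raise ValueError(f"series {s.label!r} is constant; ADF test undefined")
    maxlag = int(np.floor((len(s) - 1) ** (1 / 3)))
    stat, pval, usedlag, *_ = adfuller(s.values, maxlag=maxlag, regression=regression,
                                       autolag="AIC")
    return AdfResult(statistic=float(stat), p_value=float(pval),
                     n_lags_used=int(usedlag), stationary_at_05=bool(pval < 0.05))


def age_standardise(rates_by_age: Sequence[AnnualSeries],
                    standard_weights: Mapping[str, float]) -> AnnualSeries:
    """Directly age-standardise age-specific rates with a standard population.

    For each year the output is the weighted mean of the age-specific rates,
    with weights normalised to sum to one, so the result is invariant to
    rescaling all weights by a positive constant.  This is direct
    standardisation to a fixed standard population (e.g. the Segi world
    standard), supplied as configuration rather than hard-coded.
    """
    if not rates_by_age:
        raise ValueError("age_standardise: no input series")
    weights = []
    for s in rates_by_age:
        key = s.age_group.value
        if key not in standard_weights:
            raise ValueError(f"missing standard-population weight for age group {key!r}")
        weights.append(float(standard_weights[key]))
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("standard-population weights must be non-negative with positive sum")
    w = w / w.sum()
    aligned = align_many(list(rates_by_age))
    stacked = np.vstack([s.values for s in aligned])
    ref = aligned[0]
    from .timeseries_io import AgeGroup
    return AnnualSeries(label=ref.label, start_year=ref.start_year,
                        values=w @ stacked, unit=ref.unit, sex=ref.sex,
                        age_group=AgeGroup.ALL)
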