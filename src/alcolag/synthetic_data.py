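"""Synthetic annual study data with known ground truth.

Real aggregate alcohol–cancer studies rest on a century of registry data
that cannot be redistributed, so every downstream stage here is exercised
on simulated data generated *forwards* from the same structural model the
estimator fits:

    Δ ln M_t = α + β ΔWA_t + Σ_i μ_i ΔC_{i,t} + e_t,
    e_t = ε_t + θ ε_{t-1},   ε_t ~ N(0, σ²) i.i.d.,

with WA_t the lag-weighted exposure under a known lag profile.  MA(1)
disturbances are the default because the dominant fitted error structure in
annual log-mortality series of this kind is ARIMA(0,1,1).

Exposure trends are deterministic shapes plus small seeded noise chosen to
echo 20th-century Australian consumption histories: alcohol rises from
mid-century, plateaus around the 1970s and declines; tobacco peaks earlier
and falls more steeply; health expenditure grows monotonically.  The three
shapes are deliberately distinct — identical trends would make the
lag-weighted differenced regressors nearly collinear and the study design
unidentifiable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .lag_weights import LagWeightProfile, apply_weights, geometric_weights
from .timeseries_io import AgeGroup, AnnualSeries, Sex, StudyDataset, write_dataset

__all__ = ["SimulationConfig", "ExposureShape", "simulate_exposure",
           "simulate_mortality", "generate_study", "ALCOHOL_SHAPE",
           "TOBACCO_SHAPE", "HEALTH_SHAPE"]


@dataclass(frozen=True)
class ExposureShape:
    """Deterministic trend parameters for a simulated consumption series.

    The trend is ``base + rise·sigmoid((t−t_rise)/s_rise) −
    fall·sigmoid((t−t_fall)/s_fall)`` over year index t, i.e. a smooth
    rise-plateau-decline.  ``noise_sd`` is i.i.d. level noise added on top.
    """

    base: float
    rise: float
    t_rise: float
    s_rise: float
    fall: float
    t_fall: float
    s_fall: float
    noise_sd: float

    def trend(self, t: np.ndarray) -> np.ndarray:
        def sig(z):
            return 1.0 / (1.0 + np.exp(-z))
        return (self.base + self.rise * sig((t - self.t_rise) / self.s_rise)
                - self.fall * sig((t - self.t_fall) / self.s_fall))


#: per-capita alcohol, litres ethanol 15+: ~5 L early century, peak ~11 L
#: around the mid-1970s, decline towards ~8 L
ALCOHOL_SHAPE = ExposureShape(base=4.8, rise=8.0, t_rise=47.0, s_rise=8.0,
                              fall=5.0, t_fall=78.0, s_fall=9.0, noise_sd=0.12)
#: per-capita tobacco, kg 15+: earlier peak (~1960s) and a steep late decline
TOBACCO_SHAPE = ExposureShape(base=1.2, rise=2.2, t_rise=28.0, s_rise=9.0,
                              fall=2.6, t_fall=72.0, s_fall=9.0, noise_sd=0.05)
#: health expenditure per capita (PPP units): monotone growth, no decline
HEALTH_SHAPE = ExposureShape(base=0.3, rise=9.0, t_rise=95.0, s_rise=22.0,
                             fall=0.0, t_fall=0.0, s_fall=1.0, noise_sd=0.05)


def _default_profile() -> LagWeightProfile:
    return geometric_weights(20, 0.9)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated study.

    Defaults mirror the study conditions the package is designed around:
    109 annual observations (1910–2018), a per-litre log effect of 0.035 on
    the mortality rate, a 20-year lag profile, MA(1) disturbances with
    θ = 0.3 and innovation sd 0.005 on the Δ log scale, and a baseline
    mortality rate of 20 per 100,000.
    """

    seed: int = 0
    n_years: int = 109
    start_year: int = 1910
    beta_true: float = 0.035
    mu_tobacco: float = 0.2
    mu_health: float = -0.02
    lag_profile_true: LagWeightProfile = field(default_factory=_default_profile)
    ma1_theta: float = 0.3
    noise_sd: float = 0.005
    alpha: float = 0.0
    baseline_log_mortality: float = float(np.log(20.0))
    exposure_shape: str = "paper-like"
    flat_level: float = 10.0
    rw_step_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_years < self.lag_profile_true.max_lag + 30:
            raise ValueError("n_years must be at least the lag length + 30")


def simulate_exposure(config: SimulationConfig, *, label: str = "alcohol",
                      unit: str = "L ethanol per capita 15+",
                      shape: ExposureShape = ALCOHOL_SHAPE,
                      seed_offset: int = 0) -> AnnualSeries:
    """Simulate one non-negative annual consumption series.

    ``config.exposure_shape`` selects the generator: ``"paper-like"`` is the
    deterministic rise-plateau-decline trend of ``shape`` plus small seeded
    noise, ``"flat"`` is constant at ``config.flat_level``, and
    ``"random-walk"`` is a reflected Gaussian random walk started at
    ``config.flat_level``.  ``seed_offset`` decouples covariate noise from
    exposure noise under one study seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11, seed_offset]))
    t = np.arange(config.n_years, dtype=float)
    kind = config.exposure_shape
    if kind == "flat":
        values = np.full(config.n_years, float(config.flat_level))
    elif kind == "random-walk":
        steps = rng.normal(0.0, config.rw_step_sd, size=config.n_years)
        steps[0] = 0.0
        values = np.abs(config.flat_level + np.cumsum(steps))
    elif kind == "paper-like":
        values = shape.trend(t) + rng.normal(0.0, shape.noise_sd, size=config.n_years)
        values = np.clip(values, 0.0, None)
    else:
        raise ValueError(f"unknown exposure shape {kind!r}")
    return AnnualSeries(label=label, start_year=config.start_year, values=values,
                        unit=unit, sex=Sex.ALL, age_group=AgeGroup.ALL)


def simulate_mortality(exposure: AnnualSeries, covariates: Sequence[AnnualSeries],
                       config: SimulationConfig, *, label: str = "cancer",
                       sex: Sex | str = Sex.ALL, age_group: AgeGroup | str = AgeGroup.ALL,
                       mus: Mapping[str, float] | None = None,
                       seed_offset: int = 0) -> AnnualSeries:
    """Run the structural model forwards to produce a mortality-rate series.

    The exposure and every covariate are lag-weighted with the true profile,
    differenced, combined with coefficients β (exposure) and μ (covariates,
    looked up by label in ``mus`` with ``mu_tobacco``/``mu_health`` as
    defaults), an MA(1) disturbance is added on the Δ log scale, and the log
    series is integrated from ``baseline_log_mortality`` and exponentiated.
    The returned series starts ``max_lag`` years after the exposure does.
    """
    profile = config.lag_profile_true
    L = profile.max_lag
    if len(exposure) <= L + 2:
        raise ValueError("exposure shorter than lag length + 2")
    mu_defaults = {"tobacco": config.mu_tobacco, "health_expenditure": config.mu_health}
    mus = {**mu_defaults, **(mus or {})}

    wa = apply_weights(exposure, profile)
    d_signal = config.alpha + config.beta_true * np.diff(wa.values)
    for cov in covariates:
        if cov.label not in mus:
            raise KeyError(f"no coefficient (mu) supplied for covariate {cov.label!r}")
        wc = apply_weights(cov, profile)
        if wc.start_year > wa.start_year or wc.end_year < wa.end_year:
            raise ValueError(f"covariate {cov.label!r} does not cover the exposure window")
        dwc = np.diff(wc.window(wa.start_year, wa.end_year).values)
        d_signal = d_signal + mus[cov.label] * dwc

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23, seed_offset]))
    n_d = d_signal.size
    eps = rng.normal(0.0, config.noise_sd, size=n_d + 1)
    e = eps[1:] + config.ma1_theta * eps[:-1]

    log_m = config.baseline_log_mortality + np.concatenate([[0.0], np.cumsum(d_signal + e)])
    return AnnualSeries(label=label, start_year=wa.start_year, values=np.exp(log_m),
                        unit="deaths per 100,000", sex=sex, age_group=age_group)


# ---------------------------------------------------------------------------
# Whole-study generation


def generate_study(config: SimulationConfig,
                   outcomes: Sequence[tuple[str, Sex | str, float]] | None = None,
                   include_health_expenditure: bool = True,
                   mus: Mapping[str, float] | None = None,
                   ) -> tuple[StudyDataset, dict]:
    """Generate a full study-shaped dataset plus its ground truth.

    ``outcomes`` lists ``(cancer label, sex, beta_true)`` strata; by default
    a male and female total-cancer outcome (used downstream for lag
    identification), one UADT-like outcome per sex (both with
    ``config.beta_true``), and a lung outcome per sex with zero alcohol
    effect (the tobacco-driven negative control) are produced.  When health expenditure is included it truly
    enters the generating model over the full period, but the *recorded*
    series starts 25 years late, mimicking the shorter historical coverage
    of expenditure statistics (fits that control for it simply use fewer
    years).

    Returns ``(dataset, truth)`` where ``truth`` records every generating
    parameter needed to check an estimate.
    """
    alcohol = simulate_exposure(config, label="alcohol", shape=ALCOHOL_SHAPE,
                                seed_offset=0)
    tobacco = simulate_exposure(config, label="tobacco", unit="kg per capita 15+",
                                shape=TOBACCO_SHAPE, seed_offset=1)
    covs = [tobacco]
    series = [alcohol, tobacco]
    if include_health_expenditure:
        health = simulate_exposure(config, label="health_expenditure",
                                   unit="PPP-adjusted units per capita",
                                   shape=HEALTH_SHAPE, seed_offset=2)
        covs.append(health)
        recorded_health = health.window(config.start_year + 25, health.end_year)
        series.append(recorded_health)

    if outcomes is None:
        # lung is the negative control: tobacco-driven, no alcohol effect
        outcomes = [("total_cancer", Sex.MALE, config.beta_true),
                    ("total_cancer", Sex.FEMALE, config.beta_true),
                    ("uadt", Sex.MALE, config.beta_true),
                    ("uadt", Sex.FEMALE, config.beta_true),
                    ("lung", Sex.MALE, 0.0),
                    ("lung", Sex.FEMALE, 0.0)]

    truth: dict = {
        "beta_true": {},
        "mu_tobacco": config.mu_tobacco,
        "mu_health": config.mu_health,
        "ma1_theta": config.ma1_theta,
        "noise_sd": config.noise_sd,
        "alpha": config.alpha,
        "lag_profile_true": list(map(float, config.lag_profile_true.weights)),
        "seed": config.seed,
    }
    for i, (label, sex, beta) in enumerate(outcomes):
        out_cfg = replace(config, beta_true=beta)
        m = simulate_mortality(alcohol, covs, out_cfg, label=label, sex=sex,
                               mus=mus, seed_offset=100 + i)
        series.append(m)
        truth["beta_true"][f"{label}__{Sex(sex).value}"] = beta

    dataset = StudyDataset(series=series, metadata={"synthetic": "true",
                                                    "seed": str(config.seed)})
    return dataset, truth


def write_study(dataset: StudyDataset, truth: dict, csv_path: str | Path,
                truth_path: str | Path | None = None) -> None:
    """Write a simulated dataset plus a JSON ground-truth sidecar."""
    csv_path = Path(csv_path)
    write_dataset(dataset, csv_path)
    if truth_path is None:
        truth_path = csv_path.with_suffix(".truth.json")
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2)
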