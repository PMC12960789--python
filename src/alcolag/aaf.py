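"""Aggregate alcohol-attributable fractions (AAF) for cancer mortality.

The aggregate-data attributable fraction multiplies the average per-capita
consumption over the observation window (AACP, litres of pure ethanol per
person 15+ per year) by the estimated per-litre percent effect on the
mortality rate:

    AAF = (AACP × E) / AM = AACP × (e^β − 1) × 100,

where E is the annual mortality rate attributable to each litre and AM the
average mortality rate — AM cancels algebraically, so the fraction needs
only the consumption level and the semi-log coefficient.  Total consumption
is split between the sexes from survey evidence that males account for
about 67.5% of all alcohol consumed; with equal-sized sex populations the
sex-specific per-capita values are

    AACP_male   = AACP_total × 2 × share_male,
    AACP_female = AACP_total × 2 × (1 − share_male).

The formula is a linear approximation valid over small changes in
consumption, so computed fractions are clamped to [0, 100] with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .arimax_model import EffectEstimate
from .timeseries_io import Sex

__all__ = ["AAFInputs", "AAFResult", "sex_specific_aacp", "compute_aaf"]

#: survey-based male share of total alcohol consumption
DEFAULT_MALE_SHARE = 0.675


@dataclass(frozen=True)
class AAFInputs:
    """Inputs to an aggregate AAF computation.

    ``average_mortality`` (AM, per 100,000) is optional: it only matters for
    the intermediate E = effect × AM, which cancels in the fraction.
    """

    aacp_total: float
    effect: EffectEstimate
    male_share: float = DEFAULT_MALE_SHARE
    average_mortality: float | None = None

    def __post_init__(self) -> None:
        if self.aacp_total <= 0:
            raise ValueError("aacp_total must be positive")
        if not 0 < self.male_share < 1:
            raise ValueError("male_share must be in (0, 1)")


@dataclass(frozen=True)
class AAFResult:
    """An attributable fraction with its provenance."""

    aaf_percent: float
    sex: Sex
    aacp_sex: float
    effect_percent_per_litre: float


def sex_specific_aacp(aacp_total: float, male_share: float, sex: Sex | str,
                      sex_population_ratio: float = 1.0) -> float:
    """Split a whole-population per-capita consumption level by sex.

    ``sex_population_ratio`` is males per female in the 15+ population
    (default 1: equal sex populations).  With equal populations the male and
    female per-capita values average back to the total.
    """
    if not 0 < male_share < 1:
        raise ValueError("male_share must be in (0, 1)")
    if aacp_total <= 0:
        raise ValueError("aacp_total must be positive")
    sex = sex if isinstance(sex, Sex) else Sex(str(sex))
    r = sex_population_ratio
    # per-capita total splits over population fractions r/(1+r) male, 1/(1+r) female
    if sex is Sex.MALE:
        return aacp_total * male_share * (1 + r) / r
    if sex is Sex.FEMALE:
        return aacp_total * (1 - male_share) * (1 + r)
    return aacp_total


def compute_aaf(aacp_sex: float, effect: EffectEstimate, sex: Sex | str = Sex.NA,
                average_mortality: float | None = None) -> AAFResult:
    """Attributable fraction: sex-specific AACP × per-litre percent effect.

    When ``average_mortality`` is supplied the computation routes through
    the intermediate E = effect × AM and divides it back out — numerically
    identical to the direct product for any AM > 0.
    """
    if aacp_sex < 0:
        raise ValueError("aacp_sex must be non-negative")
    sex = sex if isinstance(sex, Sex) else Sex(str(sex))
    pct = effect.percent_per_litre
    if average_mortality is not None:
        if average_mortality <= 0:
            raise ValueError("average_mortality must be positive")
        e_intermediate = pct * average_mortality
        aaf = aacp_sex * e_intermediate / average_mortality
    else:
        aaf = aacp_sex * pct
    if aaf > 100.0 or aaf < 0.0:
        warnings.warn(
            f"AAF {aaf:.1f}% outside [0, 100]; the linear approximation does not "
            "hold this far from the observed consumption level — clamping",
            stacklevel=2,
        )
        aaf = min(max(aaf, 0.0), 100.0)
    return AAFResult(aaf_percent=float(aaf), sex=sex, aacp_sex=float(aacp_sex),
                     effect_percent_per_litre=float(pct))
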