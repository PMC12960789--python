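"""Year-indexed annual series: the universal data carrier, plus file I/O.

Every quantity in this package — per-capita alcohol consumption (litres of
pure ethanol, persons 15+), tobacco consumption (kg per capita), health
expenditure, and cause-specific cancer mortality rates per 100,000 — is an
annual series identified by a label, a sex, and an age group.  Datasets are
flat CSV files with a ``year`` column and one column per series, named
``label__sex__age`` (sex and age may be omitted for ``n/a``).  Series may
start in different years (e.g. alcohol from 1910, liver-cancer mortality
from 1968): leading/trailing blanks in a column are simply a shorter
series, while an internal blank is a hard error — these are complete annual
registry series and silent interpolation would corrupt differencing.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "AgeGroup",
    "AnnualSeries",
    "StudyDataset",
    "read_dataset",
    "write_dataset",
    "align",
    "write_report",
]

#: minimum overlap (years) required between exposure and outcome after lag
#: construction before model fitting is allowed
MIN_FIT_OVERLAP = 30


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    ALL = "all"
    NA = "n/a"


class AgeGroup(str, enum.Enum):
    A30_49 = "30-49"
    A50_69 = "50-69"
    A70P = "70+"
    ALL = "all"
    NA = "n/a"


def _coerce_sex(value: str | Sex) -> Sex:
    return value if isinstance(value, Sex) else Sex(str(value))


def _coerce_age(value: str | AgeGroup) -> AgeGroup:
    return value if isinstance(value, AgeGroup) else AgeGroup(str(value))


@dataclass(frozen=True)
class AnnualSeries:
    """One annual series: consecutive yearly values starting at ``start_year``.

    Parameters
    ----------
    label:
        Short name of the quantity, e.g. ``"alcohol"`` or ``"uadt"``.
    start_year:
        Calendar year of the first value.
    values:
        One value per consecutive year; no internal gaps.
    unit:
        Free-text unit, e.g. ``"L ethanol per capita 15+"`` or
        ``"deaths per 100,000"``.
    sex, age_group:
        Stratum identifiers; ``(label, sex, age_group)`` is the series
        identity within a dataset.
    """

    label: str
    start_year: int
    values: np.ndarray
    unit: str = ""
    sex: Sex = Sex.NA
    age_group: AgeGroup = AgeGroup.NA

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError(f"series {self.label!r}: values must be a non-empty 1-d array")
        if not np.all(np.isfinite(vals)):
            bad = int(self.start_year + np.flatnonzero(~np.isfinite(vals))[0])
            raise ValueError(f"series {self.label!r}: non-finite value at year {bad}")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "start_year", int(self.start_year))
        object.__setattr__(self, "sex", _coerce_sex(self.sex))
        object.__setattr__(self, "age_group", _coerce_age(self.age_group))

    # -- basic geometry -------------------------------------------------

    def __len__(self) -> int:
        return self.values.size

    @property
    def end_year(self) -> int:
        """Calendar year of the last value (inclusive)."""
        return self.start_year + len(self) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    @property
    def identity(self) -> tuple[str, str, str]:
        return (self.label, self.sex.value, self.age_group.value)

    # -- derived views --------------------------------------------------

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.years, name=self.label)

    def with_values(self, values: np.ndarray, *, start_year: int | None = None,
                    unit: str | None = None, label: str | None = None) -> "AnnualSeries":
        """Copy with new values (and optionally new start year / unit / label)."""
        return dataclasses.replace(
            self,
            values=np.asarray(values, dtype=float).copy(),
            start_year=self.start_year if start_year is None else start_year,
            unit=self.unit if unit is None else unit,
            label=self.label if label is None else label,
        )

    def window(self, start_year: int, end_year: int) -> "AnnualSeries":
        """Restrict to the inclusive year range [start_year, end_year]."""
        if start_year < self.start_year or end_year > self.end_year or end_year < start_year:
            raise ValueError(
                f"window {start_year}-{end_year} outside series range "
                f"{self.start_year}-{self.end_year}"
            )
        i0 = start_year - self.start_year
        return self.with_values(self.values[i0:i0 + (end_year - start_year + 1)],
                                start_year=start_year)

    def mean(self) -> float:
        return float(self.values.mean())


def align(a: AnnualSeries, b: AnnualSeries) -> tuple[AnnualSeries, AnnualSeries]:
    """Restrict two series to their common year range.

    Values are untouched; both outputs share start year and length.
    Raises ``ValueError`` when the year ranges are disjoint.
    """
    lo = max(a.start_year, b.start_year)
    hi = min(a.end_year, b.end_year)
    if hi < lo:
        raise ValueError(
            f"year ranges do not intersect: {a.label!r} {a.start_year}-{a.end_year} "
            f"vs {b.label!r} {b.start_year}-{b.end_year}"
        )
    return a.window(lo, hi), b.window(lo, hi)


def align_many(series: Sequence[AnnualSeries]) -> list[AnnualSeries]:
    """Restrict any number of series to their common year range."""
    lo = max(s.start_year for s in series)
    hi = min(s.end_year for s in series)
    if hi < lo:
        raise ValueError("year ranges of the supplied series do not intersect")
    return [s.window(lo, hi) for s in series]


@dataclass
class StudyDataset:
    """A collection of annual series plus free-form metadata."""

    series: list[AnnualSeries] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for s in self.series:
            if s.identity in seen:
                raise ValueError(f"duplicate series identity {s.identity}")
            seen.add(s.identity)

    def get(self, label: str, sex: str | Sex | None = None,
            age_group: str | AgeGroup | None = None) -> AnnualSeries:
        """Look up a series; omitted sex/age match any (must be unambiguous)."""
        want_sex = None if sex is None else _coerce_sex(sex).value
        want_age = None if age_group is None else _coerce_age(age_group).value
        hits = [s for s in self.series
                if s.label == label
                and (want_sex is None or s.sex.value == want_sex)
                and (want_age is None or s.age_group.value == want_age)]
        if not hits:
            raise KeyError(f"no series matching ({label!r}, {want_sex}, {want_age})")
        if len(hits) > 1:
            raise KeyError(f"ambiguous lookup ({label!r}, {want_sex}, {want_age}): "
                           f"{[s.identity for s in hits]}")
        return hits[0]

    def has(self, label: str, sex: str | Sex | None = None,
            age_group: str | AgeGroup | None = None) -> bool:
        try:
            self.get(label, sex, age_group)
            return True
        except KeyError:
            return False

    def add(self, s: AnnualSeries) -> None:
        if any(t.identity == s.identity for t in self.series):
            raise ValueError(f"duplicate series identity {s.identity}")
        self.series.append(s)


# ---------------------------------------------------------------------------
# CSV layout: one `year` column, one column per series named label__sex__age.


def _column_name(s: AnnualSeries) -> str:
    parts = [s.label]
    if s.sex is not Sex.NA or s.age_group is not AgeGroup.NA:
        parts.append(s.sex.value)
    if s.age_group is not AgeGroup.NA:
        parts.append(s.age_group.value)
    return "__".join(parts)


def _parse_column_name(name: str) -> tuple[str, Sex, AgeGroup]:
    parts = name.split("__")
    label = parts[0]
    sex = Sex(parts[1]) if len(parts) > 1 else Sex.NA
    age = AgeGroup(parts[2]) if len(parts) > 2 else AgeGroup.NA
    return label, sex, age


def read_dataset(path: str | Path, schema: Mapping[str, object] | None = None) -> StudyDataset:
    """Read a study dataset from a flat CSV file.

    The file must have an integer ``year`` column with consecutive,
    strictly increasing years and one column per series.  Blank cells at the
    top or bottom of a column shorten that series; a blank cell *between*
    observed values is an internal gap and raises ``ValueError``.

    ``schema`` may carry ``{"units": {label: unit}}`` to annotate units.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "year" not in df.columns:
        raise ValueError(f"{path}: no 'year' column")
    years = df["year"]
    if years.isna().any() or not np.array_equal(years.to_numpy(float), years.to_numpy(float).astype(int)):
        raise ValueError(f"{path}: malformed year column (non-integer or missing years)")
    years = years.astype(int).to_numpy()
    if len(years) > 1 and not np.all(np.diff(years) == 1):
        raise ValueError(f"{path}: year column must be consecutive and increasing")

    units = {}
    if schema:
        units = dict(schema.get("units", {}))  # type: ignore[arg-type]

    out = StudyDataset(metadata={"source_file": str(path)})
    for col in df.columns:
        if col == "year":
            continue
        vals = df[col].to_numpy(dtype=float)
        observed = np.flatnonzero(~np.isnan(vals))
        if observed.size == 0:
            continue
        lo, hi = observed[0], observed[-1]
        if np.isnan(vals[lo:hi + 1]).any():
            gap_year = int(years[lo + np.flatnonzero(np.isnan(vals[lo:hi + 1]))[0]])
            raise ValueError(f"{path}: internal gap in series {col!r} at year {gap_year}")
        label, sex, age = _parse_column_name(col)
        out.add(AnnualSeries(label=label, start_year=int(years[lo]),
                             values=vals[lo:hi + 1], unit=units.get(label, ""),
                             sex=sex, age_group=age))
    if not out.series:
        raise ValueError(f"{path}: no data columns")
    return out


def write_dataset(dataset: StudyDataset, path: str | Path) -> None:
    """Write a StudyDataset to the flat CSV layout ``read_dataset`` reads."""
    path = Path(path)
    lo = min(s.start_year for s in dataset.series)
    hi = max(s.end_year for s in dataset.series)
    years = np.arange(lo, hi + 1)
    df = pd.DataFrame({"year": years})
    for s in dataset.series:
        col = np.full(years.size, np.nan)
        col[s.start_year - lo:s.start_year - lo + len(s)] = s.values
        df[_column_name(s)] = col
    df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Report writing


_SEX_ORDER = {"male": 0, "female": 1, "all": 2, "n/a": 3}
_AGE_ORDER = {"30-49": 0, "50-69": 1, "70+": 2, "all": 3, "n/a": 4}


def write_report(results: Sequence, path: str | Path) -> None:
    """Write coefficient and AAF tables for a collection of stratum results.

    ``results`` is a sequence of :class:`alcolag.pipeline.StratumResult`
    (duck-typed: anything with ``outcome_label``, ``sex``, ``age_group``,
    ``fit``, ``effect`` and optional ``aaf``).  Two files are produced:
    ``<path>`` (CSV mirroring the layout of a per-stratum coefficient table:
    estimate, 95% CI, p-value, ARIMA order) and ``<path stem>_aaf.csv``.
    A human-readable text table is written next to them as
    ``<path stem>.txt``.
    """
    results = list(results)
    if not results:
        raise ValueError("write_report: empty results")
    path = Path(path)

    def _val(x):
        return getattr(x, "value", str(x))

    results.sort(key=lambda r: (_SEX_ORDER.get(_val(getattr(r, "sex", "n/a")), 9),
                                _AGE_ORDER.get(_val(getattr(r, "age_group", "n/a")), 9),
                                getattr(r, "outcome_label", "")))

    coef_rows = []
    aaf_rows = []
    for r in results:
        fit = r.fit
        row = {
            "outcome": r.outcome_label,
            "sex": str(getattr(r.sex, "value", r.sex)),
            "age_group": str(getattr(r.age_group, "value", r.age_group)),
            "arima_order": f"{fit.spec.p},{fit.spec.d},{fit.spec.q}",
            "estimate": fit.beta_hat,
            "ci_low": fit.ci95["beta"][0],
            "ci_high": fit.ci95["beta"][1],
            "p_value": fit.p_values["beta"],
            "q10_stat": fit.q10_stat,
            "q10_p": fit.q10_p,
            "n_obs": fit.n_obs,
            "r_squared": fit.r_squared,
        }
        for name, coef in fit.covar_coefs.items():
            row[f"coef_{name}"] = coef
            row[f"p_{name}"] = fit.p_values[name]
        if r.effect is not None:
            row["percent_per_litre"] = r.effect.percent_per_litre
        coef_rows.append(row)
        if getattr(r, "aaf", None) is not None:
            a = r.aaf
            aaf_rows.append({
                "outcome": r.outcome_label,
                "sex": str(getattr(a.sex, "value", a.sex)),
                "age_group": str(getattr(r.age_group, "value", r.age_group)),
                "aacp_sex": a.aacp_sex,
                "effect_percent_per_litre": a.effect_percent_per_litre,
                "aaf_percent": a.aaf_percent,
            })

    coef_df = pd.DataFrame(coef_rows)
    coef_df.to_csv(path, index=False, float_format="%.6g")
    aaf_path = path.with_name(path.stem + "_aaf.csv")
    pd.DataFrame(aaf_rows).to_csv(aaf_path, index=False, float_format="%.6g")

    txt_path = path.with_suffix(".txt")
    with open(txt_path, "w") as fh:
        fh.write("Coefficient table (alcohol estimate, 95% CI, p, ARIMA order)\n")
        fh.write(coef_df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        fh.write("\n\nAlcohol-attributable fractions\n")
        if aaf_rows:
            fh.write(pd.DataFrame(aaf_rows).to_string(index=False,
                                                      float_format=lambda v: f"{v:.4g}"))
        else:
            fh.write("(no significant alcohol associations; no AAFs computed)")
        fh.write("\n")
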