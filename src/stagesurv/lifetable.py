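"""Population lifetables: expected all-cause mortality rates by sex, calendar year and age.

Relative-survival methods decompose the all-cause hazard of a cancer cohort
into an expected (population) component taken from a lifetable and an excess
(cancer-attributable) component that is modelled.  This module holds the
lifetable representation and the two queries every downstream estimator needs:
the expected rate at an attained age/year, and the expected cumulative hazard
integrated along a subject's demographic diagonal (attained age and calendar
year advancing together with follow-up time).

Conventions
-----------
* Rates are per person-year and piecewise constant on half-open annual cells
  ``[age, age+1) x [year, year+1)``; fractional ages/years map to cells by
  ``floor``.
* Ages run 0-99.  An attained age of 99 or more uses the age-99 rate (the
  oldest published rate is carried over for as many years as required).
* Calendar years beyond the table's last year reuse the last year's rates,
  since registry follow-up can outrun published lifetables; the extension is
  recorded on the table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_AGE = 99
SEXES = ("female", "male")

__all__ = [
    "LifeTable",
    "synth_lifetable",
    "read_lifetable",
    "write_lifetable",
    "MAX_AGE",
    "SEXES",
]


class LifeTableLookupError(KeyError):
    """A (sex, year) combination is absent from the lifetable."""


@dataclass
class LifeTable:
    """Expected-mortality rates indexed by (sex, calendar year, age 0-99).

    Parameters
    ----------
    rates : dict
        Mapping ``sex -> 2-d array`` of shape ``(n_years, 100)`` with rates per
        person-year; row ``i`` is calendar year ``year_min + i``.
    year_min : int
        First calendar year covered.
    """

    rates: dict[str, np.ndarray]
    year_min: int
    extended_years: set[int] = field(default_factory=set, repr=False)

    def __post_init__(self) -> None:
        for sex, arr in self.rates.items():
            if sex not in SEXES:
                raise ValueError(f"unknown sex {sex!r}; expected one of {SEXES}")
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != MAX_AGE + 1:
                raise ValueError(
                    f"rates for {sex!r} must have shape (n_years, {MAX_AGE + 1}), got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"rates for {sex!r} must be finite and non-negative")
            self.rates[sex] = arr

    @property
    def year_max(self) -> int:
        n = next(iter(self.rates.values())).shape[0]
        return self.year_min + n - 1

    def _year_index(self, year: np.ndarray) -> np.ndarray:
        """Clip years above ``year_max`` to the last row (carry-forward); error below ``year_min``."""
        year = np.asarray(year)
        if np.any(year < self.year_min):
            bad = int(np.min(year))
            raise LifeTableLookupError(
                f"calendar year {bad} precedes lifetable coverage ({self.year_min}-{self.year_max})"
            )
        over = year > self.year_max
        if np.any(over):
            self.extended_years.update(np.unique(year[over]).tolist())
        return np.minimum(year, self.year_max) - self.year_min

    def expected_rate(self, sex, attained_age, year):
        """Expected mortality rate at floor(attained_age) in calendar ``year``.

        Attained ages of 99 or more use the age-99 rate.  Vectorised over
        ``attained_age`` and ``year`` for a single ``sex``.
        """
        if sex not in self.rates:
            raise LifeTableLookupError(
                f"sex {sex!r} absent from lifetable (has {sorted(self.rates)})"
            )
        age = np.asarray(attained_age, dtype=float)
        if np.any(age < 0):
            raise ValueError("attained_age must be non-negative")
        ai = np.minimum(np.floor(age).astype(int), MAX_AGE)
        yi = self._year_index(np.asarray(year, dtype=int))
        out = self.rates[sex][yi, ai]
        if np.isscalar(attained_age) and np.isscalar(year):
            return float(out)
        return out

    def expected_cumhaz(self, sex, age_at_dx, year_at_dx, t):
        """Cumulative expected hazard over ``[0, t]`` years since diagnosis.

        Integrates the piecewise-constant rate along the demographic diagonal
        (attained age ``age_at_dx + u``, attained year ``year_at_dx + u``),
        summing exactly over the annual cells the diagonal crosses.  The
        expected survival is ``exp(-result)``.
        """
        t = float(t)
        if t < 0:
            raise ValueError("t must be non-negative")
        if t == 0.0:
            return 0.0
        age0 = float(age_at_dx)
        yr0 = float(year_at_dx)
        if age0 < 0:
            raise ValueError("age_at_dx must be non-negative")
        # Cell boundaries occur where age or year crosses an integer; both
        # advance at rate 1 so breakpoints are the union of the two lattices.
        b_age = np.arange(np.ceil(age0), age0 + t) - age0
        b_year = np.arange(np.ceil(yr0), yr0 + t) - yr0
        cuts = np.unique(np.concatenate([[0.0], b_age, b_year, [t]]))
        cuts = cuts[(cuts >= 0) & (cuts <= t)]
        left = cuts[:-1]
        widths = np.diff(cuts)
        mid = left + widths / 2  # strictly inside each cell
        rates = self.expected_rate(sex, age0 + mid, np.floor(yr0 + mid).astype(int))
        return float(np.sum(np.asarray(rates) * widths))

    def expected_cumhaz_grid(self, sex, age_at_dx, year_at_dx, tgrid):
        """Vectorised ``expected_cumhaz`` for many subjects on a shared time grid.

        Parameters are arrays over subjects (same sex); ``tgrid`` is a 1-d
        increasing grid starting at a value >= 0.  Returns an array of shape
        ``(n_subjects, len(tgrid))``.  The integral is accumulated on the grid
        steps assuming the rate is constant within each step, which is exact
        when grid steps never straddle an age/year boundary and a close
        approximation otherwise (fine daily/weekly grids).
        """
        age0 = np.asarray(age_at_dx, dtype=float)[:, None]
        yr0 = np.asarray(year_at_dx, dtype=float)[:, None]
        tg = np.asarray(tgrid, dtype=float)[None, :]
        steps = np.diff(np.concatenate([[0.0], np.asarray(tgrid, dtype=float)]))
        mids = np.asarray(tgrid, dtype=float) - steps / 2
        rates = self.expected_rate(
            sex, age0 + mids[None, :], np.floor(yr0 + mids[None, :]).astype(int)
        )
        return np.cumsum(rates * steps[None, :], axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex in sorted(self.rates):
            arr = self.rates[sex]
            years = np.arange(self.year_min, self.year_min + arr.shape[0])
            yy, aa = np.meshgrid(years, np.arange(MAX_AGE + 1), indexing="ij")
            rows.append(
                pd.DataFrame(
                    {"sex": sex, "year": yy.ravel(), "age": aa.ravel(), "rate": arr.ravel()}
                )
            )
        return pd.concat(rows, ignore_index=True)


def synth_lifetable(
    base_rate: float = 1e-4,
    slope: float = 0.09,
    sex_ratio: float = 1.5,
    years: tuple[int, int] = (2005, 2027),
    calendar_drift: float = 0.0,
    seed: int | None = None,
) -> LifeTable:
    """Deterministic Gompertz-form synthetic lifetable.

    ``rate(age) = base_rate * exp(slope * age)``, multiplied by ``sex_ratio``
    for males and by ``(1 - calendar_drift)**(year - years[0])`` to emulate a
    slow secular improvement in population mortality.  ``seed`` is accepted for
    interface symmetry with the stochastic generators but unused: the table is
    a deterministic function of its arguments.
    """
    if base_rate <= 0:
        raise ValueError("base_rate must be positive")
    if slope < 0:
        raise ValueError("slope must be non-negative")
    y0, y1 = years
    ages = np.arange(MAX_AGE + 1)
    base = base_rate * np.exp(slope * ages)
    drift = (1.0 - calendar_drift) ** np.arange(y1 - y0 + 1)
    female = drift[:, None] * base[None, :]
    return LifeTable(rates={"female": female, "male": sex_ratio * female}, year_min=y0)


_SCHEMA = ("sex", "year", "age", "rate")


def read_lifetable(path_or_buf) -> LifeTable:
    """Read a lifetable CSV with columns sex, year, age and rate (or prob).

    A ``prob`` column holding annual death probabilities is converted to rates
    via ``rate = -ln(1 - prob)``.  Validation errors name the offending CSV
    line (header = line 1).
    """
    df = pd.read_csv(path_or_buf)
    cols = set(df.columns)
    if "prob" in cols and "rate" not in cols:
        p = df["prob"].to_numpy(dtype=float)
        bad = np.flatnonzero(~((p >= 0) & (p < 1)))
        if bad.size:
            raise ValueError(f"line {bad[0] + 2}: prob must be in [0, 1), got {p[bad[0]]}")
        df = df.assign(rate=-np.log1p(-p)).drop(columns="prob")
    missing = [c for c in _SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"lifetable CSV missing columns {missing}; need {list(_SCHEMA)}")
    bad_sex = np.flatnonzero(~df["sex"].isin(SEXES))
    if bad_sex.size:
        i = bad_sex[0]
        raise ValueError(f"line {i + 2}: sex must be one of {SEXES}, got {df['sex'].iloc[i]!r}")
    rate = df["rate"].to_numpy(dtype=float)
    bad = np.flatnonzero(~(np.isfinite(rate) & (rate >= 0)))
    if bad.size:
        raise ValueError(f"line {bad[0] + 2}: rate must be finite and >= 0, got {rate[bad[0]]}")

    year_min = int(df["year"].min())
    year_max = int(df["year"].max())
    n_years = year_max - year_min + 1
    rates: dict[str, np.ndarray] = {}
    for sex, sub in df.groupby("sex", sort=True):
        arr = np.full((n_years, MAX_AGE + 1), np.nan)
        arr[sub["year"].to_numpy(int) - year_min, sub["age"].to_numpy(int)] = sub[
            "rate"
        ].to_numpy(float)
        holes = np.argwhere(np.isnan(arr))
        if holes.size:
            y, a = holes[0]
            raise ValueError(
                f"lifetable incomplete: missing rate for sex={sex}, year={year_min + y}, age={a}"
            )
        rates[str(sex)] = arr
    return LifeTable(rates=rates, year_min=year_min)


def write_lifetable(lt: LifeTable, path) -> None:
    lt.to_frame().to_csv(path, index=False)


def lifetable_from_csv_text(text: str) -> LifeTable:
    """Convenience wrapper: parse a lifetable from an in-memory CSV string."""
    return read_lifetable(io.StringIO(text))
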