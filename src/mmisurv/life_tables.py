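"""Population ("expected") mortality tables.

In the relative-survival setting the observed mortality hazard of a cancer
cohort decomposes as ``lambda = lambda_E + lambda_P``, where ``lambda_P`` is
the background mortality of the general population the patients come from.
This module stores and queries that background hazard on a complete grid of
single year of age x calendar year x sex x stratum (e.g. deprivation
quintile), and integrates it exactly over the piecewise-constant cells a
patient crosses between diagnosis and a follow-up time ``t``.

Rates are annual hazards (events per person-year).  Published life tables
often give one-year death probabilities ``q_x`` instead; ``read_life_table``
converts those via ``rate = -log(1 - q_x)`` when asked.

Attained age above the table maximum is clamped to the maximum-age row
(standard registry practice); attained calendar year outside the table range
raises :class:`LifeTableCoverageError` — calendar extrapolation is never
performed silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "LifeTableStructureError",
    "LifeTableCoverageError",
    "read_life_table",
    "write_life_table",
    "expected_hazard",
    "expected_survival",
    "cumulative_expected_hazard",
    "PopulationPaths",
]

DAYS_PER_YEAR = 365.25

_STANDARD_COLUMNS = ("age", "year", "sex", "stratum", "rate")


class LifeTableStructureError(ValueError):
    """The life-table grid is incomplete or malformed."""


class LifeTableCoverageError(ValueError):
    """A query falls outside the calendar-year coverage of the table."""


@dataclass(frozen=True)
class LifeTable:
    """Complete grid of annual mortality hazards.

    ``rates`` has shape ``(n_sex, n_strata, n_ages, n_years)``; ages and
    years are contiguous integer ranges.
    """

    ages: np.ndarray
    years: np.ndarray
    sexes: tuple[str, ...]
    strata: tuple[str, ...]
    rates: np.ndarray

    def __post_init__(self) -> None:
        if self.rates.shape != (len(self.sexes), len(self.strata), len(self.ages), len(self.years)):
            raise LifeTableStructureError("rate array shape does not match axis labels")
        if not np.all(np.isfinite(self.rates)) or np.any(self.rates < 0):
            raise LifeTableStructureError("all rates must be finite and non-negative")

    # -- metadata -----------------------------------------------------------
    @property
    def age_range(self) -> tuple[int, int]:
        return int(self.ages[0]), int(self.ages[-1])

    @property
    def year_range(self) -> tuple[int, int]:
        return int(self.years[0]), int(self.years[-1])

    def _sex_index(self, sex) -> np.ndarray:
        lut = {s: i for i, s in enumerate(self.sexes)}
        try:
            return np.asarray([lut[str(s)] for s in np.atleast_1d(sex)])
        except KeyError as exc:
            raise LifeTableStructureError(f"unknown sex label {exc.args[0]!r}; table has {self.sexes}")

    def _stratum_index(self, stratum) -> np.ndarray:
        lut = {s: i for i, s in enumerate(self.strata)}
        try:
            return np.asarray([lut[str(s)] for s in np.atleast_1d(stratum)])
        except KeyError as exc:
            raise LifeTableStructureError(
                f"unknown stratum label {exc.args[0]!r}; table has {self.strata}"
            )

    # -- lookup -------------------------------------------------------------
    def rate_at(self, age, year, sex, stratum) -> np.ndarray:
        """Vectorised cell lookup; age clamped, year strictly checked."""
        age = np.atleast_1d(np.asarray(age))
        year = np.atleast_1d(np.asarray(year))
        a = np.clip(np.floor(age).astype(int), self.ages[0], self.ages[-1])
        y = np.floor(year).astype(int)
        lo, hi = self.year_range
        if np.any((y < lo) | (y > hi)):
            bad = int(y[(y < lo) | (y > hi)][0])
            raise LifeTableCoverageError(
                f"calendar year {bad} outside life-table coverage {lo}-{hi}"
            )
        si = self._sex_index(sex)
        zi = self._stratum_index(stratum)
        si, zi, a, y = np.broadcast_arrays(si, zi, a, y)
        return self.rates[si, zi, a - self.ages[0], y - self.years[0]]

    def to_frame(self) -> pd.DataFrame:
        sx, zx, ax, yx = np.meshgrid(
            np.arange(len(self.sexes)),
            np.arange(len(self.strata)),
            np.arange(len(self.ages)),
            np.arange(len(self.years)),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "age": self.ages[ax.ravel()],
                "year": self.years[yx.ravel()],
                "sex": np.asarray(self.sexes)[sx.ravel()],
                "stratum": np.asarray(self.strata)[zx.ravel()],
                "rate": self.rates.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        df = df.copy()
        for col in _STANDARD_COLUMNS:
            if col not in df.columns:
                raise LifeTableStructureError(f"life table missing required column {col!r}")
        df["age"] = df["age"].astype(int)
        df["year"] = df["year"].astype(int)
        df["sex"] = df["sex"].astype(str)
        df["stratum"] = df["stratum"].astype(str)
        df["rate"] = pd.to_numeric(df["rate"], errors="raise")
        if (df["rate"] < 0).any():
            bad = df.loc[df["rate"] < 0].iloc[0]
            raise LifeTableStructureError(
                f"negative rate {bad['rate']} at (age={bad['age']}, year={bad['year']}, "
                f"sex={bad['sex']}, stratum={bad['stratum']})"
            )
        ages = np.arange(df["age"].min(), df["age"].max() + 1)
        years = np.arange(df["year"].min(), df["year"].max() + 1)
        sexes = tuple(sorted(df["sex"].unique()))
        strata = tuple(sorted(df["stratum"].unique()))
        if df.duplicated(subset=["age", "year", "sex", "stratum"]).any():
            dup = df[df.duplicated(subset=["age", "year", "sex", "stratum"])].iloc[0]
            raise LifeTableStructureError(
                f"duplicate life-table cell (age={dup['age']}, year={dup['year']}, "
                f"sex={dup['sex']}, stratum={dup['stratum']})"
            )
        rates = np.full((len(sexes), len(strata), len(ages), len(years)), np.nan)
        si = df["sex"].map({s: i for i, s in enumerate(sexes)}).to_numpy()
        zi = df["stratum"].map({s: i for i, s in enumerate(strata)}).to_numpy()
        rates[si, zi, df["age"].to_numpy() - ages[0], df["year"].to_numpy() - years[0]] = df[
            "rate"
        ].to_numpy()
        if np.isnan(rates).any():
            s, z, a, y = [idx[0] for idx in np.nonzero(np.isnan(rates))]
            raise LifeTableStructureError(
                f"incomplete life-table grid: missing cell (age={ages[a]}, year={years[y]}, "
                f"sex={sexes[s]}, stratum={strata[z]})"
            )
        return cls(ages=ages, years=years, sexes=sexes, strata=strata, rates=rates)


def read_life_table(path, column_map: dict | None = None, rate_type: str = "hazard") -> LifeTable:
    """Read a delimited life-table file (comma or tab, autodetected).

    ``column_map`` renames nonstandard headers onto the standard
    ``age, year, sex, stratum, rate`` set, e.g. ``{"dep": "stratum"}``.
    ``rate_type="qx"`` converts one-year death probabilities to hazards.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if column_map:
        df = df.rename(columns=column_map)
    if "stratum" not in df.columns:
        df["stratum"] = "all"
    if rate_type == "qx":
        q = pd.to_numeric(df["rate"], errors="raise")
        if ((q < 0) | (q >= 1)).any():
            raise LifeTableStructureError("q_x probabilities must lie in [0, 1)")
        df["rate"] = -np.log1p(-q)
    elif rate_type != "hazard":
        raise ValueError(f"unknown rate_type {rate_type!r}")
    return LifeTable.from_frame(df)


def write_life_table(table: LifeTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# piecewise-constant integration along patient trajectories
# ---------------------------------------------------------------------------


class PopulationPaths:
    """Per-subject cumulative expected hazard, exact over life-table cells.

    For subject ``i`` diagnosed at continuous age ``a_i`` and decimal
    calendar date ``d_i``, the background hazard at follow-up time ``u`` is
    the table rate at ``(floor(a_i+u), floor(d_i+u))``: piecewise constant
    with breakpoints wherever attained age or attained year crosses an
    integer.  The cumulative hazard is therefore continuous piecewise linear;
    this class precomputes the segments up to a per-subject horizon so that
    evaluation and inversion are vectorised.
    """

    def __init__(self, table: LifeTable, age, date, sex, stratum, horizon) -> None:
        age = np.atleast_1d(np.asarray(age, dtype=float))
        date = np.atleast_1d(np.asarray(date, dtype=float))
        horizon = np.broadcast_to(np.asarray(horizon, dtype=float), age.shape).copy()
        sex = np.broadcast_to(np.atleast_1d(np.asarray(sex, dtype=object)), age.shape)
        stratum = np.broadcast_to(np.atleast_1d(np.asarray(stratum, dtype=object)), age.shape)
        n = age.size
        breaks_list, rates_list = [], []
        for i in range(n):
            h = max(horizon[i], 0.0)
            bp = _cell_breakpoints(age[i], date[i], h)
            r = table.rate_at(age[i] + bp, date[i] + bp, sex[i], stratum[i])
            breaks_list.append(bp)
            rates_list.append(np.asarray(r, dtype=float))
        m = max(len(b) for b in breaks_list)
        self.breaks = np.full((n, m), np.inf)
        self.rates = np.zeros((n, m))
        for i, (b, r) in enumerate(zip(breaks_list, rates_list)):
            self.breaks[i, : len(b)] = b
            self.rates[i, : len(b)] = r
            if len(b) < m:  # pad with the last segment's rate so eval clamps
                self.rates[i, len(b) :] = r[-1]
        seg_len = np.diff(np.where(np.isfinite(self.breaks), self.breaks, 0.0), axis=1)
        seg_len = np.maximum(seg_len, 0.0)
        self.cum = np.concatenate(
            [np.zeros((n, 1)), np.cumsum(self.rates[:, :-1] * seg_len, axis=1)], axis=1
        )
        self.horizon = horizon

    def cumhaz_at(self, t) -> np.ndarray:
        """Cumulative expected hazard at per-subject times ``t`` (shape (n,))."""
        t = np.asarray(t, dtype=float)
        idx = np.clip((self.breaks <= t[:, None]).sum(axis=1) - 1, 0, self.breaks.shape[1] - 1)
        rows = np.arange(self.breaks.shape[0])
        return self.cum[rows, idx] + self.rates[rows, idx] * (t - self.breaks[rows, idx])

    def cumhaz_grid(self, times, chunk: int = 128) -> np.ndarray:
        """Cumulative expected hazard of every subject at every grid time.

        Returns shape ``(n_subjects, len(times))``; evaluated in chunks to
        bound memory.
        """
        times = np.asarray(times, dtype=float)
        n, m = self.breaks.shape
        out = np.empty((n, times.size))
        rows = np.arange(n)[:, None]
        for s in range(0, times.size, chunk):
            tc = times[s : s + chunk]
            idx = np.clip(
                (self.breaks[:, :, None] <= tc[None, None, :]).sum(axis=1) - 1, 0, m - 1
            )
            out[:, s : s + tc.size] = (
                np.take_along_axis(self.cum, idx, axis=1)
                + np.take_along_axis(self.rates, idx, axis=1)
                * (tc[None, :] - np.take_along_axis(self.breaks, idx, axis=1))
            )
        return out

    def invert(self, e) -> np.ndarray:
        """Solve ``cumhaz(t) = e`` per subject; ``inf`` beyond the horizon."""
        e = np.asarray(e, dtype=float)
        idx = np.clip((self.cum <= e[:, None]).sum(axis=1) - 1, 0, self.cum.shape[1] - 1)
        rows = np.arange(self.cum.shape[0])
        rate = self.rates[rows, idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.breaks[rows, idx] + (e - self.cum[rows, idx]) / rate
        t = np.where(rate <= 0, np.inf, t)
        return np.where(t > self.horizon, np.inf, t)


def _cell_breakpoints(age: float, date: float, horizon: float) -> np.ndarray:
    """Follow-up times in [0, horizon) at which a life-table cell boundary is crossed."""
    pts = [0.0]
    for start in (age, date):
        first = np.ceil(start) - start
        if first <= 0:
            first = 1.0
        pts.extend(np.arange(first, horizon, 1.0))
    bp = np.unique(np.asarray(pts))
    return bp[bp < max(horizon, np.finfo(float).tiny)]


# ---------------------------------------------------------------------------
# scalar conveniences
# ---------------------------------------------------------------------------


def expected_hazard(
    table: LifeTable, age_at_diagnosis, year_of_diagnosis, sex, stratum, t
) -> np.ndarray:
    """Background hazard at attained age/year ``(floor(a+t), floor(y+t))``."""
    t = np.asarray(t, dtype=float)
    return table.rate_at(
        np.asarray(age_at_diagnosis, dtype=float) + t,
        np.asarray(year_of_diagnosis, dtype=float) + t,
        sex,
        stratum,
    )


def cumulative_expected_hazard(
    table: LifeTable, age_at_diagnosis, year_of_diagnosis, sex, stratum, t
):
    """Exact integral of the background hazard from diagnosis to ``t``."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    paths = PopulationPaths(
        table,
        age_at_diagnosis,
        year_of_diagnosis,
        sex,
        stratum,
        horizon=float(np.max(t_arr)) + 1e-9,
    )
    n = paths.breaks.shape[0]
    if n == 1:
        vals = paths.cumhaz_grid(np.atleast_1d(t_arr))[0]
        return float(vals[0]) if t_arr.ndim == 0 else vals
    return paths.cumhaz_at(np.broadcast_to(t_arr, (n,)))


def expected_survival(table: LifeTable, age_at_diagnosis, year_of_diagnosis, sex, stratum, t):
    """Expected (population) survival ``S_P(t) = exp(-int_0^t lambda_P du)``."""
    return np.exp(-cumulative_expected_hazard(table, age_at_diagnosis, year_of_diagnosis, sex, stratum, t))
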