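"""Calendar-indexed temperature and phenology containers.

Every module in the package shares one day-index convention: offsets are
signed integers relative to 1 January of the *event year*, with Jan 1 = 1
and Dec 31 of the preceding year = 0.  Ordinal dates below 1 therefore
refer to the previous calendar year, which is where autumn/winter chilling
covariates live.  Offsets are computed by true calendar arithmetic, so leap
years are handled exactly over multi-century series.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DailyTemperatureSeries",
    "PhenologySeries",
    "to_day_index",
    "from_day_index",
    "read_temperature_csv",
    "write_temperature_csv",
    "read_phenology_csv",
    "write_phenology_csv",
    "read_deltas_csv",
    "write_deltas_csv",
    "extract_covariates",
    "covariate_matrix",
    "JUN1_PREV_OFFSET",
    "SEP1_PREV_OFFSET",
    "NOV1_PREV_OFFSET",
]

#: Offsets of the conventional anchor dates in the preceding year.  These are
#: exact for every year: Feb 29 can only fall between Jan 1 of the event year
#: and a date *after* it, never between a preceding-year date and Jan 1.
JUN1_PREV_OFFSET = -213
SEP1_PREV_OFFSET = -121
NOV1_PREV_OFFSET = -60


def to_day_index(date: dt.date, event_year: int) -> int:
    """Signed day offset of *date* relative to Jan 1 of *event_year* (Jan 1 = 1).

    Dec 31 of the preceding year maps to 0 and earlier dates to negative
    offsets, matching the ordinal-date convention in which values < 1 refer
    to the previous year.
    """
    if isinstance(date, dt.datetime):
        date = date.date()
    offset = (date - dt.date(event_year, 1, 1)).days + 1
    if date.year > event_year:
        raise ValueError(
            f"{date} lies after the end of event year {event_year}"
        )
    return offset


def from_day_index(offset: int, event_year: int) -> dt.date:
    """Inverse of :func:`to_day_index`."""
    return dt.date(event_year, 1, 1) + dt.timedelta(days=int(offset) - 1)


@dataclass
class DailyTemperatureSeries:
    """Daily mean temperatures on a strictly increasing daily calendar.

    Internally a pandas Series on a complete daily DatetimeIndex; days that
    were absent from the source file are present in the index but NaN, so
    gaps are explicit rather than silently skipped.
    """

    data: pd.Series

    def __post_init__(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("DailyTemperatureSeries requires a DatetimeIndex")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicated date in temperature series: {dup.date()}")
        if not idx.is_monotonic_increasing:
            raise ValueError("temperature dates must be strictly increasing")
        # reindex onto the complete daily grid so gaps are explicit NaNs
        full = pd.date_range(idx[0], idx[-1], freq="D")
        self.data = self.data.reindex(full).astype(float)
        finite = self.data.dropna()
        if not np.isfinite(finite.to_numpy()).all():
            raise ValueError("temperatures must be finite")

    @classmethod
    def from_records(cls, dates, temps) -> "DailyTemperatureSeries":
        s = pd.Series(np.asarray(temps, dtype=float), index=pd.DatetimeIndex(dates))
        return cls(s)

    @property
    def start(self) -> dt.date:
        return self.data.index[0].date()

    @property
    def end(self) -> dt.date:
        return self.data.index[-1].date()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().sum())

    def __len__(self) -> int:
        return len(self.data)

    def value_on(self, date: dt.date) -> float:
        return float(self.data.loc[pd.Timestamp(date)])

    def shifted(self, monthly_delta: np.ndarray) -> "DailyTemperatureSeries":
        """Return a copy with ``monthly_delta[month-1]`` added to every day."""
        monthly_delta = np.asarray(monthly_delta, dtype=float)
        if monthly_delta.shape != (12,):
            raise ValueError("monthly_delta must have 12 entries (Jan..Dec)")
        add = monthly_delta[self.data.index.month.to_numpy() - 1]
        return DailyTemperatureSeries(self.data + add)


@dataclass
class PhenologySeries:
    """Annual first-event dates for one species.

    ``events`` maps event year -> ordinal event day (Jan 1 = 1).  At most one
    observation per year; event days lie in [1, 366].  Years where a forward
    simulation produced no event by its horizon are kept in ``no_event_years``
    so downstream summaries can account for them.
    """

    species: str
    events: dict[int, int] = field(default_factory=dict)
    no_event_years: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        for year, day in self.events.items():
            if not 1 <= day <= 366:
                raise ValueError(
                    f"{self.species} {year}: event day {day} outside [1, 366]"
                )
        overlap = set(self.events) & self.no_event_years
        if overlap:
            raise ValueError(f"years both observed and no-event: {sorted(overlap)}")

    @property
    def years(self) -> np.ndarray:
        return np.array(sorted(self.events), dtype=int)

    @property
    def days(self) -> np.ndarray:
        return np.array([self.events[y] for y in sorted(self.events)], dtype=float)

    @property
    def last_event_day(self) -> int:
        return int(max(self.events.values()))

    def __len__(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# CSV I/O.  File schemas:
#   temperatures.csv: date (ISO-8601), temp_c
#   phenology.csv:    species, year, ordinal_day
#   deltas.csv:       sample_id, month (1-12), delta_c
# ---------------------------------------------------------------------------

def read_temperature_csv(path) -> DailyTemperatureSeries:
    df = pd.read_csv(path)
    required = {"date", "temp_c"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        # locate the first offending row for a useful message
        for i, v in enumerate(df["date"]):
            try:
                pd.Timestamp(v)
            except (ValueError, TypeError):
                raise ValueError(f"{path}: unparseable date on data row {i + 1}: {v!r}") from exc
        raise
    if dates.duplicated().any():
        first = df["date"][dates.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated date {first}")
    if not dates.is_monotonic_increasing:
        raise ValueError(f"{path}: dates are not monotone increasing")
    return DailyTemperatureSeries.from_records(dates, df["temp_c"].to_numpy(float))


def write_temperature_csv(series: DailyTemperatureSeries, path) -> None:
    kept = series.data.dropna()
    pd.DataFrame(
        {"date": kept.index.strftime("%Y-%m-%d"), "temp_c": kept.to_numpy()}
    ).to_csv(path, index=False)


def read_phenology_csv(path) -> dict[str, PhenologySeries]:
    df = pd.read_csv(path)
    required = {"species", "year", "ordinal_day"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    out: dict[str, PhenologySeries] = {}
    for species, grp in df.groupby("species", sort=True):
        if grp["year"].duplicated().any():
            year = int(grp["year"][grp["year"].duplicated()].iloc[0])
            raise ValueError(f"{path}: duplicate observation for {species} {year}")
        events = {}
        no_event = set()
        for _, row in grp.iterrows():
            if pd.isna(row["ordinal_day"]):
                no_event.add(int(row["year"]))
            else:
                events[int(row["year"])] = int(row["ordinal_day"])
        out[str(species)] = PhenologySeries(str(species), events, no_event)
    return out


def write_phenology_csv(series_by_species, path) -> None:
    rows = []
    for sp, ps in series_by_species.items():
        for y in sorted(ps.events):
            rows.append((sp, y, ps.events[y]))
        for y in sorted(ps.no_event_years):
            rows.append((sp, y, np.nan))
    pd.DataFrame(rows, columns=["species", "year", "ordinal_day"]).to_csv(
        path, index=False
    )


def read_deltas_csv(path) -> np.ndarray:
    """Read monthly temperature-change samples into an (n_samples, 12) array."""
    df = pd.read_csv(path)
    required = {"sample_id", "month", "delta_c"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    wide = df.pivot(index="sample_id", columns="month", values="delta_c")
    missing = set(range(1, 13)) - set(wide.columns)
    if missing or wide.isna().any().any():
        raise ValueError(f"{path}: every sample needs all 12 months")
    return wide.loc[:, range(1, 13)].to_numpy(float)


def write_deltas_csv(deltas: np.ndarray, path) -> None:
    deltas = np.asarray(deltas, dtype=float)
    n, m = deltas.shape
    if m != 12:
        raise ValueError("deltas must have 12 columns")
    rows = [
        (i, month + 1, deltas[i, month]) for i in range(n) for month in range(12)
    ]
    pd.DataFrame(rows, columns=["sample_id", "month", "delta_c"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Covariate extraction
# ---------------------------------------------------------------------------

def extract_covariates(
    series: DailyTemperatureSeries,
    event_year: int,
    start_offset: int,
    end_offset: int,
) -> np.ndarray:
    """Daily temperatures for one event year over [start_offset, end_offset].

    Offsets follow the package day-index convention.  Raises if any day in
    the range is outside the series or flagged missing: window scans must
    never be computed over silently imputed temperatures.
    """
    if end_offset < start_offset:
        raise ValueError("end_offset must be >= start_offset")
    d0 = pd.Timestamp(from_day_index(start_offset, event_year))
    d1 = pd.Timestamp(from_day_index(end_offset, event_year))
    idx = series.data.index
    if d0 < idx[0] or d1 > idx[-1]:
        raise ValueError(
            f"temperature series ({idx[0].date()}..{idx[-1].date()}) does not cover "
            f"offsets [{start_offset}, {end_offset}] of event year {event_year} "
            f"({d0.date()}..{d1.date()})"
        )
    chunk = series.data.loc[d0:d1]
    if chunk.isna().any():
        gap = chunk.index[chunk.isna()][0].date()
        raise ValueError(f"missing temperature on {gap} within requested window")
    values = chunk.to_numpy(float)
    assert len(values) == end_offset - start_offset + 1
    return values


def covariate_matrix(
    series: DailyTemperatureSeries,
    event_years,
    start_offset: int,
    end_offset: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-year covariate vectors into a (n_years, n_days) matrix.

    Returns ``(X, offsets)`` where column j of X holds the temperature at
    ``offsets[j]`` for each event year.  This offset-aligned matrix is the
    covariate container shared by the window scan, the signal regression and
    the thermal-time models.
    """
    offsets = np.arange(start_offset, end_offset + 1)
    X = np.empty((len(event_years), len(offsets)), dtype=float)
    for i, year in enumerate(event_years):
        X[i] = extract_covariates(series, int(year), start_offset, end_offset)
    return X, offsets
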