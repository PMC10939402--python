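"""Temperature and LT50 table I/O, plus hourly-temperature estimation.

Field weather archives usually carry daily minimum/maximum air temperature,
while every cumulative cold-hardiness descriptor (chilling, growing degree
hours, moving averages) is defined on an hourly grid.  This module reads the
two CSV schemas used throughout the package and expands daily min/max records
into an idealized 24-hour diurnal curve.

All timestamps are local standard time (no DST shifts): the downstream
features are fixed 24-hour window sums and a spring-forward gap would corrupt
them.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DailyWeather",
    "TemperatureSeries",
    "LT50Record",
    "WeatherValidationError",
    "SchemaError",
    "read_daily_weather",
    "read_lt50",
    "interpolate_hourly",
    "fill_daily_gaps",
]

# Diurnal-curve anchors (hours, local standard time).  The daytime branch is a
# sine rising from the morning minimum at sunrise to the maximum at TMAX_HOUR;
# the night branch decays logarithmically toward the next morning's minimum.
SUNRISE_HOUR = 6
TMAX_HOUR = 14
SUNSET_HOUR = 18


class SchemaError(ValueError):
    """A required column is missing or the file cannot be parsed."""


class WeatherValidationError(ValueError):
    """Rows violate an invariant (tmin > tmax, duplicate dates, ...)."""


@dataclass(frozen=True)
class DailyWeather:
    """One day of min/max air temperature (°C) at a site."""

    date: Date
    tmin: float
    tmax: float
    latitude: float | None = None

    def __post_init__(self) -> None:
        if self.tmin > self.tmax:
            raise WeatherValidationError(
                f"{self.date}: tmin ({self.tmin}) exceeds tmax ({self.tmax})"
            )


@dataclass(frozen=True)
class TemperatureSeries:
    """Hourly temperatures (°C) on a strictly increasing timestamp grid."""

    timestamps: pd.DatetimeIndex
    temp: np.ndarray
    site_id: str = "site"

    def __post_init__(self) -> None:
        t = np.asarray(self.temp, dtype=float)
        object.__setattr__(self, "temp", t)
        if len(t) != len(self.timestamps):
            raise ValueError("timestamps and temp have different lengths")
        if len(t) % 24 != 0:
            raise ValueError("series must cover whole days (24 values each)")
        if not self.timestamps.is_monotonic_increasing or self.timestamps.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite temperature values")

    def __len__(self) -> int:
        return len(self.temp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.timestamps, "temp": self.temp, "site": self.site_id}
        )


@dataclass(frozen=True)
class LT50Record:
    """A single bud-LT50 observation (°C, negative) for one cultivar/date/site."""

    date: Date
    site_id: str
    cultivar: str
    lt50: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.lt50):
            raise WeatherValidationError(f"{self.date}/{self.cultivar}: non-finite lt50")


_DEFAULT_WEATHER_DIALECT = {"date": "date", "tmin": "tmin", "tmax": "tmax"}


def read_daily_weather(
    path, dialect: dict[str, str] | None = None, permissive: bool = False
) -> list[DailyWeather]:
    """Read a daily min/max CSV into validated, date-sorted records.

    ``dialect`` maps the canonical names (date, tmin, tmax, optionally
    latitude) onto the file's column headers.  In permissive mode interior
    gaps of up to three days are linearly imputed (and logged); in strict
    mode any gap raises :class:`WeatherValidationError`.
    """
    cols = dict(_DEFAULT_WEATHER_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path)
    missing = [c for c in (cols["date"], cols["tmin"], cols["tmax"]) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")

    lat_col = cols.get("latitude")
    records = []
    bad: list[str] = []
    for _, row in df.iterrows():
        d = pd.Timestamp(row[cols["date"]]).date()
        tmin, tmax = float(row[cols["tmin"]]), float(row[cols["tmax"]])
        if tmin > tmax:
            bad.append(str(d))
            continue
        lat = float(row[lat_col]) if lat_col and lat_col in df.columns else None
        records.append(DailyWeather(d, tmin, tmax, lat))
    if bad:
        raise WeatherValidationError(f"tmin > tmax on date(s): {', '.join(bad)}")

    records.sort(key=lambda r: r.date)
    dates = [r.date for r in records]
    if len(set(dates)) != len(dates):
        dupes = sorted({d for d in dates if dates.count(d) > 1})
        raise WeatherValidationError(f"duplicate date(s): {dupes}")
    return fill_daily_gaps(records, permissive=permissive)


def fill_daily_gaps(
    records: list[DailyWeather], permissive: bool = False, max_run: int = 3
) -> list[DailyWeather]:
    """Impute short interior gaps (permissive) or raise on any gap (strict)."""
    if not records:
        return records
    out = [records[0]]
    for rec in records[1:]:
        prev = out[-1]
        gap = (rec.date - prev.date).days - 1
        if gap > 0:
            if not permissive or gap > max_run:
                raise WeatherValidationError(
                    f"missing daily record(s) between {prev.date} and {rec.date}"
                )
            logger.info("imputing %d missing day(s) after %s", gap, prev.date)
            for k in range(1, gap + 1):
                w = k / (gap + 1)
                out.append(
                    DailyWeather(
                        prev.date + timedelta(days=k),
                        prev.tmin * (1 - w) + rec.tmin * w,
                        prev.tmax * (1 - w) + rec.tmax * w,
                        prev.latitude,
                    )
                )
        out.append(rec)
    return out


def read_lt50(path, roster=None) -> tuple[list[LT50Record], list[LT50Record]]:
    """Read LT50 observations; returns (records, flagged-unknown-cultivar).

    Expected columns: date, site, cultivar, lt50.  Unparseable lt50 values
    raise with the offending row index; unknown cultivars (when a roster is
    supplied) are returned separately rather than dropped.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            logger.warning("%s: empty LT50 file", path)
            return [], []
        required = {"date", "site", "cultivar", "lt50"}
        if not required.issubset(reader.fieldnames):
            raise SchemaError(
                f"{path}: need columns {sorted(required)}, found {reader.fieldnames}"
            )
        records, flagged = [], []
        for i, row in enumerate(reader):
            try:
                lt50 = float(row["lt50"])
            except (TypeError, ValueError) as exc:
                raise WeatherValidationError(
                    f"{path} row {i}: unparseable lt50 {row['lt50']!r}"
                ) from exc
            rec = LT50Record(
                pd.Timestamp(row["date"]).date(), row["site"], row["cultivar"], lt50
            )
            if roster is not None and rec.cultivar not in set(roster):
                flagged.append(rec)
            else:
                records.append(rec)
    if not records and not flagged:
        logger.warning("%s: no LT50 rows", path)
    return records, flagged


def _day_profile(tmin: float, tmax: float, prev_sunset_temp: float, next_tmin: float) -> np.ndarray:
    """24 hourly values for one day given its neighbours' anchor temperatures."""
    hours = np.arange(24)
    temp = np.empty(24)

    # pre-dawn: tail of the previous night's decay, ending at tmin at sunrise
    night_len = 24 - SUNSET_HOUR + SUNRISE_HOUR  # hours from sunset to next sunrise
    for h in range(SUNRISE_HOUR):
        k = h + (24 - SUNSET_HOUR)  # hours since previous sunset
        frac = math.log1p(k) / math.log1p(night_len)
        temp[h] = prev_sunset_temp + (tmin - prev_sunset_temp) * frac

    # daytime sine: tmin at sunrise, tmax at TMAX_HOUR
    day_span = 2 * (TMAX_HOUR - SUNRISE_HOUR)  # half-period of the sine
    day = (hours >= SUNRISE_HOUR) & (hours <= SUNSET_HOUR)
    temp[day] = tmin + (tmax - tmin) * np.sin(np.pi * (hours[day] - SUNRISE_HOUR) / day_span)

    # evening: logarithmic decay from the sunset temperature toward next tmin
    sunset_temp = tmin + (tmax - tmin) * math.sin(
        math.pi * (SUNSET_HOUR - SUNRISE_HOUR) / day_span
    )
    for h in range(SUNSET_HOUR + 1, 24):
        k = h - SUNSET_HOUR
        frac = math.log1p(k) / math.log1p(night_len)
        temp[h] = sunset_temp + (next_tmin - sunset_temp) * frac
    return temp


def interpolate_hourly(daily: list[DailyWeather], site_id: str = "site") -> TemperatureSeries:
    """Estimate hourly temperatures from daily min/max (idealized diurnal curve).

    Daytime follows a sine from the sunrise minimum to the mid-afternoon
    maximum; night-time decays logarithmically toward the next morning's
    minimum.  The first and last days are anchored by virtual neighbours equal
    to themselves, so a block of identical days yields identical 24-h profiles.
    """
    if not daily:
        raise ValueError("interpolate_hourly: empty input")
    dates = [r.date for r in daily]
    if any((b - a).days != 1 for a, b in zip(dates, dates[1:])):
        raise WeatherValidationError("daily records must be consecutive calendar days")

    day_span = 2 * (TMAX_HOUR - SUNRISE_HOUR)
    sunset_frac = math.sin(math.pi * (SUNSET_HOUR - SUNRISE_HOUR) / day_span)

    blocks = []
    for i, rec in enumerate(daily):
        prev = daily[i - 1] if i > 0 else rec
        nxt = daily[i + 1] if i + 1 < len(daily) else rec
        prev_sunset = prev.tmin + (prev.tmax - prev.tmin) * sunset_frac
        blocks.append(_day_profile(rec.tmin, rec.tmax, prev_sunset, nxt.tmin))

    temp = np.concatenate(blocks)
    ts = pd.date_range(pd.Timestamp(dates[0]), periods=len(temp), freq="h")
    return TemperatureSeries(ts, temp, site_id)
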