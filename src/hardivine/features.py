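"""The 117-feature representation of a (site, date, cultivar) sample.

A labelled bud-LT50 observation is described by:

* 45 Boolean cultivar indicators (one-hot over the roster),
* days in season (days elapsed since 1 September),
* that day's mean/max/min temperature (°C),
* cumulative descriptors from season start: Utah and North-Carolina chill
  units, 0–7.2 °C chill hours, growing degree hours at four base
  temperatures, and freezing degree hours (magnitude of sub-zero exposure),
* 60 exponentially weighted moving averages: EWMA and REWMA of the daily
  mean, max and min temperature at window sizes 2, 4, ..., 20 days.

EWMA weights the most recent day of a trailing window most; REWMA reverses
the window first, so the *oldest* day weighs most — a representation of cold
priming, where earlier exposure conditions the later response.  All
accumulators reset at 1 September, the start of the dormancy season.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from datetime import date as Date

import numpy as np
import pandas as pd

from .weather_io import TemperatureSeries

__all__ = [
    "CultivarRoster",
    "DEFAULT_ROSTER",
    "FeatureConfig",
    "WINDOW_SIZES",
    "WINDOW_STATISTICS",
    "one_hot_cultivar",
    "days_in_season",
    "season_start",
    "ewma",
    "rewma",
    "utah_chill",
    "nc_chill",
    "chill_hours",
    "gdh",
    "freezing_degree_hours",
    "season_feature_table",
    "assemble_features",
    "build_feature_matrix",
    "feature_names",
]

WINDOW_SIZES: tuple[int, ...] = (2, 4, 6, 8, 10, 12, 14, 16, 18, 20)
WINDOW_STATISTICS: tuple[str, ...] = ("mean", "max", "min")

# Richardson et al. (1974) Utah chill-unit weights per hour, stepwise in °C.
# Upper band edges paired with the weight for temperatures at or below them.
UTAH_CHILL_TABLE: tuple[tuple[float, float], ...] = (
    (1.4, 0.0),
    (2.4, 0.5),
    (9.1, 1.0),
    (12.4, 0.5),
    (15.9, 0.0),
    (18.0, -0.5),
    (np.inf, -1.0),
)

# Shaltout & Unrath (1983) North Carolina chill-unit weights, stepwise form.
NC_CHILL_TABLE: tuple[tuple[float, float], ...] = (
    (-1.1, 0.0),
    (1.6, 0.5),
    (7.2, 1.0),
    (13.0, 0.5),
    (16.5, 0.0),
    (19.0, -0.5),
    (20.7, -1.0),
    (22.1, -1.5),
    (np.inf, -2.0),
)

CHILL_HOURS_RANGE = (0.0, 7.2)  # count hours with 0 < T <= 7.2 °C
GDH_BASES: tuple[float, ...] = (0.0, 4.0, 7.0, 10.0)


@dataclass(frozen=True)
class CultivarRoster:
    """Ordered, unique cultivar names; order is part of any trained artifact."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("roster names must be unique")
        object.__setattr__(self, "names", tuple(self.names))

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        return self.names.index(name)


# The study roster: 24 cold-hardy interspecific hybrids and 21 V. vinifera.
DEFAULT_ROSTER = CultivarRoster(
    (
        # hybrids
        "Brianna", "Catawba", "Cayuga White", "Chambourcin", "Chancellor",
        "Chardonel", "Concord", "Corot Noir", "Delaware", "Elvira",
        "Frontenac", "Geneva Red", "Itasca", "La Crescent", "La Crosse",
        "Leon Millot", "Marechal Foch", "Marquette", "Niagara", "Noiret",
        "Seyval Blanc", "St. Croix", "Traminette", "Vidal Blanc",
        # V. vinifera
        "Cabernet Franc", "Cabernet Sauvignon", "Chardonnay", "Dornfelder",
        "Gamay Noir", "Gewurztraminer", "Gruner Veltliner", "Lemberger",
        "Malbec", "Merlot", "Muscat Ottonel", "Pinot Gris", "Pinot Noir",
        "Riesling", "Sangiovese", "Sauvignon Blanc", "Semillon", "Syrah",
        "Tempranillo", "Viognier", "Zinfandel",
    )
)


@dataclass(frozen=True)
class FeatureConfig:
    """Temperature-feature composition (overridable; defaults give 72 columns,
    i.e. 117 total with the 45-cultivar roster)."""

    windows: tuple[int, ...] = WINDOW_SIZES
    statistics: tuple[str, ...] = WINDOW_STATISTICS
    gdh_bases: tuple[float, ...] = GDH_BASES


DEFAULT_CONFIG = FeatureConfig()


def one_hot_cultivar(name: str, roster: CultivarRoster) -> np.ndarray:
    """Boolean indicator vector over the roster; exactly one position is 1."""
    if name not in roster:
        close = difflib.get_close_matches(name, list(roster), n=3)
        hint = f"; did you mean {close}?" if close else ""
        raise KeyError(f"unknown cultivar {name!r}{hint}")
    vec = np.zeros(len(roster), dtype=int)
    vec[roster.index(name)] = 1
    return vec


def season_start(date: Date) -> Date:
    """1 September opening the dormancy season containing ``date``."""
    year = date.year if date.month >= 9 else date.year - 1
    return Date(year, 9, 1)


def days_in_season(date: Date) -> int:
    """Days elapsed since 1 September (0 on 1 Sept; Jan–Aug use previous year)."""
    return (date - season_start(date)).days


def _window_weights(m: int, n: int) -> np.ndarray:
    # span convention: alpha = 2/(n+1); weight (1-alpha)^lag, newest lag 0
    alpha = 2.0 / (n + 1)
    w = (1.0 - alpha) ** np.arange(m)
    return w / w.sum()


def ewma(values, n: int) -> float:
    """Normalized exponentially weighted mean of the trailing ``n``-day window.

    The newest value carries the largest weight.  If fewer than ``n`` values
    are available the weights are renormalized over what exists.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("ewma: empty window")
    v = v[-n:]
    w = _window_weights(v.size, n)
    return float(np.dot(w, v[::-1]))


def rewma(values, n: int) -> float:
    """EWMA of the reversed window: the oldest day weighs most."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("rewma: empty window")
    return ewma(v[-n:][::-1], n)


def _moving_series(daily: np.ndarray, n: int, reverse: bool) -> np.ndarray:
    """EWMA/REWMA over every trailing window of the daily series (vectorized
    for full windows; the first n−1 entries renormalize over what exists)."""
    m = len(daily)
    out = np.empty(m)
    head = min(n - 1, m)
    for i in range(head):
        window = daily[: i + 1]
        out[i] = rewma(window, n) if reverse else ewma(window, n)
    if m >= n:
        w = _window_weights(n, n)  # newest-first
        windows = np.lib.stride_tricks.sliding_window_view(daily, n)
        out[n - 1:] = windows @ (w if reverse else w[::-1])
    return out


def _step_weights(temps: np.ndarray, table) -> np.ndarray:
    bounds = np.array([b for b, _ in table])
    weights = np.array([w for _, w in table])
    return weights[np.searchsorted(bounds, temps, side="left")]


def _hours_through(series: TemperatureSeries, through: Date) -> np.ndarray:
    mask = series.timestamps.date <= through
    start = season_start(through)
    mask &= series.timestamps.date >= start
    return series.temp[mask]


def utah_chill(series: TemperatureSeries, through: Date) -> float:
    """Cumulative Utah (Richardson) chill units from 1 Sept through ``through``."""
    return float(_step_weights(_hours_through(series, through), UTAH_CHILL_TABLE).sum())


def nc_chill(series: TemperatureSeries, through: Date) -> float:
    """Cumulative North Carolina (Shaltout–Unrath) chill units."""
    return float(_step_weights(_hours_through(series, through), NC_CHILL_TABLE).sum())


def chill_hours(series: TemperatureSeries, through: Date) -> float:
    """Hours with 0 °C < T <= 7.2 °C since season start."""
    t = _hours_through(series, through)
    lo, hi = CHILL_HOURS_RANGE
    return float(((t > lo) & (t <= hi)).sum())


def gdh(series: TemperatureSeries, through: Date, base: float = 10.0) -> float:
    """Growing degree hours: sum of max(0, T - base) since season start."""
    t = _hours_through(series, through)
    return float(np.maximum(0.0, t - base).sum())


def freezing_degree_hours(series: TemperatureSeries, through: Date) -> float:
    """Magnitude of sub-zero exposure: sum of max(0, -T) since season start."""
    t = _hours_through(series, through)
    return float(np.maximum(0.0, -t).sum())


def temperature_feature_names(config: FeatureConfig = DEFAULT_CONFIG) -> list[str]:
    names = ["days_in_season", "t_mean", "t_max", "t_min",
             "chill_utah", "chill_nc", "chill_hours"]
    names += [f"gdh_base{int(b)}" for b in config.gdh_bases]
    names += ["fdh"]
    for prefix in ("ewma", "rewma"):
        for stat in config.statistics:
            for n in config.windows:
                names.append(f"{prefix}_{stat}_{n:02d}")
    return names


def feature_names(
    roster: CultivarRoster = DEFAULT_ROSTER, config: FeatureConfig = DEFAULT_CONFIG
) -> list[str]:
    """Full ordered column list: cultivar bits first, then temperature features."""
    return [f"cv_{name}" for name in roster] + temperature_feature_names(config)


def season_feature_table(
    series: TemperatureSeries, config: FeatureConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Per-date temperature features for every day covered by ``series``.

    Cumulative descriptors (chilling, GDH, FDH, days in season) reset at each
    1 September; the moving averages run over the contiguous daily aggregates,
    renormalizing over whatever history exists in the first days.
    """
    df = pd.DataFrame({"temp": series.temp}, index=series.timestamps)
    daily = df["temp"].resample("D").agg(["mean", "max", "min"])
    dates = np.array([d.date() for d in daily.index])

    out = pd.DataFrame(index=pd.Index(dates, name="date"))
    out["days_in_season"] = [days_in_season(d) for d in dates]
    out["t_mean"] = daily["mean"].to_numpy()
    out["t_max"] = daily["max"].to_numpy()
    out["t_min"] = daily["min"].to_numpy()

    # hourly accumulators, reset at season boundaries
    hour_dates = series.timestamps.date
    seasons = np.array([season_start(d) for d in dates])
    hourly_tables = {
        "chill_utah": _step_weights(series.temp, UTAH_CHILL_TABLE),
        "chill_nc": _step_weights(series.temp, NC_CHILL_TABLE),
        "chill_hours": (
            (series.temp > CHILL_HOURS_RANGE[0]) & (series.temp <= CHILL_HOURS_RANGE[1])
        ).astype(float),
        "fdh": np.maximum(0.0, -series.temp),
    }
    for b in config.gdh_bases:
        hourly_tables[f"gdh_base{int(b)}"] = np.maximum(0.0, series.temp - b)

    day_of_hour = pd.Index(hour_dates)
    for name, contrib in hourly_tables.items():
        per_day = pd.Series(contrib).groupby(day_of_hour).sum()
        per_day = per_day.reindex(dates, fill_value=0.0)
        cum = (
            pd.Series(per_day.to_numpy(), index=out.index)
            .groupby(seasons)
            .cumsum()
        )
        out[name] = cum.to_numpy()

    for prefix, reverse in (("ewma", False), ("rewma", True)):
        for stat in config.statistics:
            base = daily[stat].to_numpy(dtype=float)
            for n in config.windows:
                out[f"{prefix}_{stat}_{n:02d}"] = _moving_series(base, n, reverse)

    # column order contract
    return out[temperature_feature_names(config)]


def assemble_features(
    series: TemperatureSeries,
    cultivar: str,
    date: Date,
    roster: CultivarRoster = DEFAULT_ROSTER,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> pd.Series:
    """The full feature vector (117 entries with defaults) for one sample."""
    table = season_feature_table(series, config)
    if date not in table.index:
        raise ValueError(f"no hourly coverage for {date} in series {series.site_id!r}")
    onehot = pd.Series(
        one_hot_cultivar(cultivar, roster), index=[f"cv_{n}" for n in roster]
    )
    vec = pd.concat([onehot, table.loc[date]])
    vec.name = (series.site_id, date, cultivar)
    return vec.astype(float)


def build_feature_matrix(
    series_by_site: dict[str, TemperatureSeries],
    samples: pd.DataFrame,
    roster: CultivarRoster = DEFAULT_ROSTER,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Vectorized featurization of many (site, date, cultivar) samples.

    ``samples`` needs columns site, date, cultivar.  The per-site feature
    table is computed once and joined, so cost scales with days + samples.
    """
    missing_sites = set(samples["site"]) - set(series_by_site)
    if missing_sites:
        raise ValueError(f"no temperature series for site(s) {sorted(missing_sites)}")

    tables = {s: season_feature_table(ts, config) for s, ts in series_by_site.items()}
    cv_cols = [f"cv_{n}" for n in roster]
    rows = []
    for site, date, cultivar in samples[["site", "date", "cultivar"]].itertuples(index=False):
        table = tables[site]
        if date not in table.index:
            raise ValueError(f"no hourly coverage for {date} at site {site!r}")
        rows.append(
            np.concatenate([one_hot_cultivar(cultivar, roster), table.loc[date].to_numpy()])
        )
    return pd.DataFrame(
        np.asarray(rows, dtype=float),
        columns=cv_cols + temperature_feature_names(config),
        index=samples.index,
    )
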