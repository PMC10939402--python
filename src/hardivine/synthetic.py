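"""Synthetic multi-site, multi-cultivar weather and bud-LT50 benchmarks.

The generator provides known-structure data so the whole pipeline is
testable without any download:

* **Weather** — daily min/max per site: a calendar sinusoid (coldest in
  mid-January) plus AR(1) synoptic deviations, with a jittered diurnal
  range.  Full years are generated so multi-season series are contiguous.

* **LT50 dynamics** — a daily discrete-dynamic latent trajectory per
  cultivar: acclimation (hardening) proportional to how far the daily mean
  sits below a threshold, deacclimation proportional to warmth above it
  gated by a logistic function of accumulated chill (buds deacclimate
  readily only once chilling is satisfied), clamped between the cultivar's
  initial LT50 and its maximum hardiness.  Observations are the latent
  values at sampling dates plus Gaussian noise.

The dynamics are deliberately *not* the inverse of the feature set (no
EWMA, no Utah weights), so a model that predicts well on this benchmark has
genuinely extracted the temperature signal rather than inverted the
features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as Date
from datetime import timedelta

import numpy as np
import pandas as pd

from .features import DEFAULT_ROSTER, CultivarRoster, build_feature_matrix, season_start
from .model import HardinessDataset
from .weather_io import DailyWeather, interpolate_hourly

__all__ = [
    "ClimateSpec",
    "CultivarDynamics",
    "SyntheticDataset",
    "simulate_weather",
    "simulate_lt50",
    "make_benchmark",
    "to_hardiness_dataset",
    "write_benchmark_csvs",
]

MIDWINTER_DOY = 15  # 15 January, coldest day of the climatological year


@dataclass(frozen=True)
class ClimateSpec:
    """Site climate: sinusoidal seasonal course + AR(1) daily deviations."""

    mean_winter_tmin: float = -12.0  # °C, baseline tmin at mid-January
    seasonal_amplitude: float = 12.0  # °C, half peak-to-peak of the sinusoid
    diurnal_range: float = 8.0  # °C, mean tmax − tmin
    ar1: float = 0.7  # day-to-day persistence of deviations
    noise_sd: float = 3.0  # °C, AR(1) innovation SD

    def __post_init__(self) -> None:
        if not 0 <= self.ar1 < 1:
            raise ValueError("AR(1) coefficient must be in [0, 1)")
        if self.noise_sd < 0 or self.diurnal_range < 0:
            raise ValueError("spreads must be nonnegative")

    def baseline_tmin(self, date: Date) -> float:
        phase = 2 * np.pi * (date.timetuple().tm_yday - MIDWINTER_DOY) / 365.0
        return self.mean_winter_tmin + self.seasonal_amplitude * (1 - np.cos(phase))


@dataclass(frozen=True)
class CultivarDynamics:
    """Daily acclimation/deacclimation parameters for one cultivar."""

    name: str
    initial_lt50: float = -9.0  # °C, early-autumn (and ceiling) hardiness
    max_hardiness: float = -28.0  # °C, floor the cultivar can reach
    acclimation_rate: float = 0.05  # °C gained per day per °C below threshold
    deacclimation_rate: float = 0.12  # °C lost per day per °C above threshold
    threshold: float = 10.0  # °C, daily-mean pivot between gain and loss
    chilling_requirement: float = 60.0  # chill days to half-release deacclimation
    chill_scale: float = 10.0  # chill days, width of the logistic release

    def __post_init__(self) -> None:
        if not self.max_hardiness < self.initial_lt50 < 0:
            raise ValueError("need max_hardiness < initial_lt50 < 0")
        if self.acclimation_rate <= 0 or self.deacclimation_rate <= 0:
            raise ValueError("rates must be positive")


@dataclass
class SyntheticDataset:
    """Observations + latent ground truth + everything needed to regenerate."""

    weather: dict[str, list[DailyWeather]]
    observations: pd.DataFrame  # date, site, cultivar, lt50
    latent: pd.DataFrame  # date, site, cultivar, lt50_latent
    cultivars: list[CultivarDynamics]
    climates: dict[str, ClimateSpec]
    obs_noise_sd: float
    seed: int


def simulate_weather(
    spec: ClimateSpec,
    n_seasons: int,
    seed: int = 0,
    start_year: int = 2015,
) -> list[DailyWeather]:
    """Contiguous daily weather from 1 Sept ``start_year`` through 30 Apr of
    the last season (full intervening years, so seasons remain contiguous)."""
    if n_seasons < 1:
        raise ValueError("n_seasons must be >= 1")
    start = Date(start_year, 9, 1)
    end = Date(start_year + n_seasons, 4, 30)
    n_days = (end - start).days + 1

    rng = np.random.default_rng(seed)
    records = []
    dev = 0.0
    for k in range(n_days):
        d = start + timedelta(days=k)
        dev = spec.ar1 * dev + rng.normal(0.0, spec.noise_sd)
        tmin = spec.baseline_tmin(d) + dev
        # diurnal-range jitter scales with the innovation SD so the
        # zero-noise limit degenerates to an exactly periodic sinusoid
        span = max(0.0, spec.diurnal_range + rng.normal(0.0, spec.noise_sd / 3.0))
        records.append(DailyWeather(d, tmin, tmin + span))
    return records


def _chill_day(t_mean: float) -> float:
    return 1.0 if 0.0 < t_mean <= 7.2 else 0.0


def simulate_lt50(
    weather: list[DailyWeather],
    dynamics: CultivarDynamics,
    obs_noise_sd: float,
    sampling_dates,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the daily hardiness dynamics over ``weather``.

    Returns (observations at sampling_dates with noise, full latent
    trajectory).  The latent state resets to ``initial_lt50`` at each
    1 September.
    """
    rng = np.random.default_rng(seed)
    h = dynamics.initial_lt50
    chill = 0.0
    current_season = None
    lat_dates, lat_vals = [], []
    for rec in weather:
        s = season_start(rec.date)
        if s != current_season:
            current_season = s
            h = dynamics.initial_lt50
            chill = 0.0
        t_mean = 0.5 * (rec.tmin + rec.tmax)
        chill += _chill_day(t_mean)
        if t_mean < dynamics.threshold:
            h -= dynamics.acclimation_rate * (dynamics.threshold - t_mean)
            h = max(h, dynamics.max_hardiness)
        elif t_mean > dynamics.threshold:
            gate = 1.0 / (
                1.0
                + np.exp(-(chill - dynamics.chilling_requirement) / dynamics.chill_scale)
            )
            h += dynamics.deacclimation_rate * (t_mean - dynamics.threshold) * gate
            h = min(h, dynamics.initial_lt50)
        lat_dates.append(rec.date)
        lat_vals.append(h)

    latent = pd.DataFrame(
        {"date": lat_dates, "cultivar": dynamics.name, "lt50_latent": lat_vals}
    )
    lookup = dict(zip(lat_dates, lat_vals))
    obs_rows = []
    for d in sampling_dates:
        if d not in lookup:
            raise ValueError(f"sampling date {d} outside weather coverage")
        obs_rows.append(
            {
                "date": d,
                "cultivar": dynamics.name,
                "lt50": lookup[d] + rng.normal(0.0, obs_noise_sd),
            }
        )
    return pd.DataFrame(obs_rows), latent


def _default_cultivar_set(n: int, uniform: bool) -> list[CultivarDynamics]:
    hybrids = [n_ for n_ in DEFAULT_ROSTER][:24]
    vinifera = [n_ for n_ in DEFAULT_ROSTER][24:]
    out = []
    for i in range(n):
        hardy = i % 2 == 0
        name = hybrids[i // 2] if hardy else vinifera[i // 2]
        if uniform:
            out.append(CultivarDynamics(name=name))
        elif hardy:
            # hybrid-like: deep hardiness, fast acclimation and deacclimation
            out.append(
                CultivarDynamics(
                    name=name,
                    initial_lt50=-9.0 - 0.3 * i,
                    max_hardiness=-30.0 - 0.5 * i,
                    acclimation_rate=0.06 + 0.004 * i,
                    deacclimation_rate=0.16,
                )
            )
        else:
            # vinifera-like: shallower hardiness, slower dynamics
            out.append(
                CultivarDynamics(
                    name=name,
                    initial_lt50=-8.0 - 0.3 * i,
                    max_hardiness=-23.0 - 0.5 * i,
                    acclimation_rate=0.035 + 0.003 * i,
                    deacclimation_rate=0.10,
                )
            )
    return out


def _sampling_dates(start_year: int, n_seasons: int) -> dict[int, list[Date]]:
    """Weekly sampling 1 Oct – mid-April per season."""
    out = {}
    for s in range(n_seasons):
        first = Date(start_year + s, 10, 1)
        last = Date(start_year + s + 1, 4, 15)
        dates, d = [], first
        while d <= last:
            dates.append(d)
            d += timedelta(days=7)
        out[s] = dates
    return out


def make_benchmark(
    n_sites: int = 4,
    n_cultivars: int = 5,
    n_seasons: int = 4,
    seed: int = 0,
    obs_noise_sd: float = 1.0,
    uniform_cultivars: bool = False,
    start_year: int = 2015,
) -> SyntheticDataset:
    """Crossed site × cultivar × season benchmark with latent ground truth.

    Sites span a gradient of winter severity; cultivars alternate hardy
    (hybrid-like) and tender (vinifera-like) dynamics unless
    ``uniform_cultivars`` removes all between-cultivar differences (the
    null-control configuration).  Weekly sampling from 1 Oct to mid-April
    gives ~29 observations per site-cultivar-season.
    """
    rng = np.random.default_rng(seed)
    climates = {
        f"site{i:02d}": ClimateSpec(mean_winter_tmin=-16.0 + 2.5 * i)
        for i in range(n_sites)
    }
    cultivars = _default_cultivar_set(n_cultivars, uniform_cultivars)
    per_season = _sampling_dates(start_year, n_seasons)
    all_dates = [d for dates in per_season.values() for d in dates]

    weather, obs_frames, latent_frames = {}, [], []
    for site, spec in climates.items():
        w_seed = int(rng.integers(0, 2**31 - 1))
        weather[site] = simulate_weather(spec, n_seasons, seed=w_seed, start_year=start_year)
        for dyn in cultivars:
            o_seed = int(rng.integers(0, 2**31 - 1))
            obs, latent = simulate_lt50(
                weather[site], dyn, obs_noise_sd, all_dates, seed=o_seed
            )
            obs["site"] = site
            latent["site"] = site
            obs_frames.append(obs)
            latent_frames.append(latent)

    observations = pd.concat(obs_frames, ignore_index=True)[
        ["date", "site", "cultivar", "lt50"]
    ]
    latent = pd.concat(latent_frames, ignore_index=True)[
        ["date", "site", "cultivar", "lt50_latent"]
    ]
    return SyntheticDataset(
        weather, observations, latent, cultivars, climates, obs_noise_sd, seed
    )


def to_hardiness_dataset(
    ds: SyntheticDataset, roster: CultivarRoster = DEFAULT_ROSTER
) -> HardinessDataset:
    """Featurize a synthetic benchmark into the K × 117 labelled dataset."""
    series = {
        site: interpolate_hourly(days, site_id=site) for site, days in ds.weather.items()
    }
    X = build_feature_matrix(series, ds.observations, roster)
    y = ds.observations["lt50"].rename("lt50")
    meta = ds.observations[["date", "site", "cultivar"]].copy()
    meta["season"] = [str(season_start(d).year) for d in meta["date"]]
    return HardinessDataset(X.reset_index(drop=True), y.reset_index(drop=True), meta)


def write_benchmark_csvs(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Emit the CSV schemas the I/O layer reads, plus the ground-truth sidecar."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for site, days in ds.weather.items():
        p = outdir / f"weather_{site}.csv"
        pd.DataFrame(
            {"date": [r.date for r in days],
             "tmin": [r.tmin for r in days],
             "tmax": [r.tmax for r in days]}
        ).to_csv(p, index=False)
        paths[f"weather_{site}"] = str(p)
    p = outdir / "lt50.csv"
    ds.observations.to_csv(p, index=False)
    paths["lt50"] = str(p)
    p = outdir / "lt50_latent.csv"
    ds.latent.to_csv(p, index=False)
    paths["latent"] = str(p)
    return paths
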