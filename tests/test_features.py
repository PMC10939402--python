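"""Feature engineering: one-hot, season clock, EWMA/REWMA, chilling, GDH."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hardivine.features import (
    DEFAULT_ROSTER,
    CultivarRoster,
    assemble_features,
    build_feature_matrix,
    chill_hours,
    days_in_season,
    ewma,
    feature_names,
    freezing_degree_hours,
    gdh,
    nc_chill,
    one_hot_cultivar,
    rewma,
    utah_chill,
)
from hardivine.weather_io import DailyWeather, TemperatureSeries, interpolate_hourly


def hours_at(temps, start=dt.datetime(2020, 11, 1), pad_value=-5.0):
    """TemperatureSeries with the given hourly values, padded to whole days.

    The pad temperature defaults to -5 degC, which contributes zero to every
    chilling/GDH accumulator under test, so partial-day inputs stay exact.
    """
    temps = list(temps)
    pad = (-len(temps)) % 24
    temps = temps + [pad_value] * pad
    ts = pd.date_range(start, periods=len(temps), freq="h")
    return TemperatureSeries(ts, np.array(temps, dtype=float))


def brute_force_ewma(window, n):
    """Independent oracle: explicit weight enumeration, newest day heaviest."""
    alpha = 2.0 / (n + 1)
    w = [(1 - alpha) ** lag for lag in range(len(window))]  # lag 0 = newest
    total = sum(w)
    return sum(wi * v for wi, v in zip(w, reversed(window))) / total


class TestOneHot:
    def test_position(self):
        roster = CultivarRoster(("A", "B", "C"))
        np.testing.assert_array_equal(one_hot_cultivar("B", roster), [0, 1, 0])

    def test_sums_to_one_for_every_roster_member(self):
        for name in DEFAULT_ROSTER:
            assert one_hot_cultivar(name, DEFAULT_ROSTER).sum() == 1

    def test_typo_suggests_nearest(self):
        with pytest.raises(KeyError, match="Riesling"):
            one_hot_cultivar("Reisling", DEFAULT_ROSTER)

    def test_duplicate_roster_rejected(self):
        with pytest.raises(ValueError):
            CultivarRoster(("A", "A"))


class TestDaysInSeason:
    @pytest.mark.parametrize(
        "date,expected",
        [
            (dt.date(2020, 9, 1), 0),
            (dt.date(2020, 9, 2), 1),
            (dt.date(2021, 1, 1), 122),
            (dt.date(2021, 8, 31), (dt.date(2021, 8, 31) - dt.date(2020, 9, 1)).days),
        ],
    )
    def test_calendar_arithmetic(self, date, expected):
        assert days_in_season(date) == expected


class TestEwmaRewma:
    def test_constant_series(self):
        for n in (2, 10, 20):
            assert ewma([3.5] * n, n) == pytest.approx(3.5)
            assert rewma([3.5] * n, n) == pytest.approx(3.5)

    def test_two_value_window_hand_computed(self):
        # n=2, alpha=2/3: weights 0.75 (newest) and 0.25 (oldest)
        assert ewma([10.0, 20.0], 2) == pytest.approx(17.5)
        assert rewma([10.0, 20.0], 2) == pytest.approx(12.5)

    @pytest.mark.parametrize("n", range(2, 21, 2))
    def test_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        window = rng.normal(0, 10, size=n)
        assert ewma(window, n) == pytest.approx(brute_force_ewma(list(window), n), abs=1e-12)
        assert rewma(window, n) == pytest.approx(
            brute_force_ewma(list(window[::-1]), n), abs=1e-12
        )

    def test_rewma_is_ewma_of_reversed_window(self):
        rng = np.random.default_rng(0)
        for n in range(2, 21):
            w = rng.normal(size=n)
            assert rewma(w, n) == pytest.approx(ewma(w[::-1], n), abs=1e-12)

    def test_short_history_renormalizes(self):
        # only 3 of 10 days available: weights renormalize over the 3
        assert ewma([1.0, 2.0, 3.0], 10) == pytest.approx(
            brute_force_ewma([1.0, 2.0, 3.0], 10), abs=1e-12
        )

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(-40, 40), min_size=2, max_size=20),
        st.sampled_from(range(2, 21, 2)),
    )
    def test_convexity_bounds(self, window, n):
        w = window[-n:]
        assert min(w) - 1e-9 <= ewma(window, n) <= max(w) + 1e-9
        assert min(w) - 1e-9 <= rewma(window, n) <= max(w) + 1e-9

    def test_monotone_window_ordering(self):
        inc = list(range(10))
        dec = inc[::-1]
        for n in (2, 6, 10):
            assert ewma(inc, n) > rewma(inc, n)
            assert ewma(dec, n) < rewma(dec, n)

    def test_surrogate_alpha_limits(self):
        # alpha -> 0 recovers the arithmetic mean; alpha -> 1 the newest value
        from hardivine.features import _window_weights

        v = np.array([4.0, 8.0, 1.0, 7.0])
        w_flat = np.full(4, 0.25)
        assert np.dot(w_flat, v[::-1]) == pytest.approx(v.mean())
        # large n makes alpha = 2/(n+1) small: weights approach uniform
        w = _window_weights(4, 10_000)
        assert np.dot(w, v[::-1]) == pytest.approx(v.mean(), rel=1e-3)
        # n=1 gives alpha=1: all weight on the newest value
        assert ewma(v, 1) == pytest.approx(v[-1])


class TestChillingAndHeat:
    def test_utah_published_bands(self):
        d = dt.date(2020, 11, 1)
        assert utah_chill(hours_at([5.0] * 10), d) == pytest.approx(10.0)
        assert utah_chill(hours_at([-5.0] * 10), d) == pytest.approx(0.0)
        assert utah_chill(hours_at([20.0] * 5 + [-5.0] * 5), d) == pytest.approx(-5.0)
        # half-weight bands
        assert utah_chill(hours_at([2.0] * 4 + [-5.0] * 4), d) == pytest.approx(2.0)
        assert utah_chill(hours_at([10.0] * 4 + [-5.0] * 4), d) == pytest.approx(2.0)

    def test_nc_published_bands(self):
        d = dt.date(2020, 11, 1)
        assert nc_chill(hours_at([-10.0] * 10), d) == pytest.approx(0.0)
        # optimum band (1.6, 7.2] has unit weight
        assert nc_chill(hours_at([5.0] * 10), d) == pytest.approx(10.0)
        # strong negation above 22.1 degC
        assert nc_chill(hours_at([25.0] * 2 + [-10.0] * 2), d) == pytest.approx(-4.0)

    def test_chill_hours_threshold(self):
        d = dt.date(2020, 11, 1)
        assert chill_hours(hours_at([5.0] * 10), d) == 10
        assert chill_hours(hours_at([10.0] * 10), d) == 0
        assert chill_hours(hours_at([3.0] * 5 + [9.0] * 5), d) == 5

    def test_gdh(self):
        d = dt.date(2020, 11, 1)
        assert gdh(hours_at([5.0] * 10), d, base=10.0) == 0.0
        assert gdh(hours_at([12.0] * 10), d, base=10.0) == pytest.approx(20.0)

    def test_freezing_degree_hours(self):
        d = dt.date(2020, 11, 1)
        assert freezing_degree_hours(
            hours_at([-3.0] * 4 + [5.0] * 4, pad_value=5.0), d
        ) == pytest.approx(12.0)

    def test_accumulators_additive_over_time_partitions(self):
        rng = np.random.default_rng(3)
        temps = rng.uniform(-15, 25, size=24 * 9)
        series = hours_at(temps, start=dt.datetime(2020, 10, 1))
        mid = dt.date(2020, 10, 4)
        end = dt.date(2020, 10, 9)
        for f in (utah_chill, nc_chill, chill_hours, freezing_degree_hours):
            whole = f(series, end)
            first = f(series, mid)
            # tail contribution = hours after `mid`
            tail_series = hours_at(
                temps[24 * 4:], start=dt.datetime(2020, 10, 5)
            )
            assert whole == pytest.approx(first + f(tail_series, end), abs=1e-9)

    def test_gdh_nondecreasing_in_time(self):
        rng = np.random.default_rng(4)
        temps = rng.uniform(-10, 20, size=24 * 6)
        series = hours_at(temps, start=dt.datetime(2020, 10, 1))
        vals = [gdh(series, dt.date(2020, 10, 1) + dt.timedelta(days=k)) for k in range(6)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


@pytest.fixture(scope="module")
def season_series():
    rng = np.random.default_rng(11)
    days = []
    d0 = dt.date(2020, 9, 1)
    for i in range(120):
        tmin = 10 - 0.15 * i + rng.normal(0, 2)
        days.append(DailyWeather(d0 + dt.timedelta(days=i), tmin, tmin + 8))
    return interpolate_hourly(days, site_id="geneva")


class TestAssembly:
    def test_117_features_one_cultivar_bit(self, season_series):
        vec = assemble_features(season_series, "Riesling", dt.date(2020, 12, 1))
        assert len(vec) == 117
        cv = vec[[c for c in vec.index if c.startswith("cv_")]]
        assert len(cv) == 45 and cv.sum() == 1 and cv["cv_Riesling"] == 1
        assert vec.notna().all()

    def test_ewma_block_has_60_entries(self):
        names = feature_names()
        assert sum(n.startswith(("ewma_", "rewma_")) for n in names) == 60
        assert len(names) == len(set(names)) == 117

    def test_deterministic(self, season_series):
        a = assemble_features(season_series, "Concord", dt.date(2020, 11, 15))
        b = assemble_features(season_series, "Concord", dt.date(2020, 11, 15))
        pd.testing.assert_series_equal(a, b)

    def test_uncovered_date_raises(self, season_series):
        with pytest.raises(ValueError, match="coverage"):
            assemble_features(season_series, "Riesling", dt.date(2021, 6, 1))

    def test_matrix_matches_single_assembly(self, season_series):
        samples = pd.DataFrame(
            {
                "site": ["geneva", "geneva"],
                "date": [dt.date(2020, 11, 1), dt.date(2020, 12, 15)],
                "cultivar": ["Riesling", "Concord"],
            }
        )
        M = build_feature_matrix({"geneva": season_series}, samples)
        assert M.shape == (2, 117)
        row0 = assemble_features(season_series, "Riesling", dt.date(2020, 11, 1))
        np.testing.assert_allclose(M.iloc[0].to_numpy(), row0.to_numpy())

    def test_season_reset_of_accumulators(self):
        # two seasons back to back: accumulators restart at 1 September
        days = [
            DailyWeather(dt.date(2020, 8, 25) + dt.timedelta(days=i), 5.0, 5.0)
            for i in range(14)
        ]
        series = interpolate_hourly(days)
        before = utah_chill(series, dt.date(2020, 8, 31))
        after = utah_chill(series, dt.date(2020, 9, 1))
        assert before == pytest.approx(7 * 24)
        assert after == pytest.approx(24)  # only 1 Sept counts in the new season
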