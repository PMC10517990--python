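"""Exposure metrics: cold-run day counts vs a brute-force oracle,
activity windows, performance summaries, min-max normalization."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thermoscape as ts
from thermoscape.errors import ContiguityError, DegenerateRangeError
from thermoscape.exposure import run_day_count
from thermoscape.hourly import HourlyDay

from conftest import PARABOLA_LOW


def brute_force_cold_days(temps, threshold, min_run, hours_per_day=24):
    """Enumerate every maximal below-threshold run by linear scan and mark
    the calendar days it touches — the independent oracle."""
    marked = set()
    i = 0
    n = len(temps)
    while i < n:
        if temps[i] < threshold:
            j = i
            while j < n and temps[j] < threshold:
                j += 1
            if j - i >= min_run:
                for k in range(i, j):
                    marked.add(k // hours_per_day)
            i = j
        else:
            i += 1
    return len(marked)


def hourly_series(temps, start="2002-01-01"):
    idx = pd.date_range(start, periods=len(temps), freq="h")
    return pd.Series(np.asarray(temps, dtype=float), index=idx)


class TestColdExposureDays:
    def test_all_warm_counts_nothing(self):
        assert ts.cold_exposure_days(hourly_series([20.0] * 96), 9.0) == 0

    def test_single_contained_run_counts_one_day(self):
        temps = np.full(48, 20.0)
        temps[30:36] = 5.0  # 6 h inside day 2
        assert ts.cold_exposure_days(hourly_series(temps), 9.0) == 1

    def test_midnight_spanning_run_counts_both_days(self):
        temps = np.full(72, 20.0)
        temps[21:27] = 5.0  # 21:00 day 1 – 03:00 day 2
        assert ts.cold_exposure_days(hourly_series(temps), 9.0) == 2

    def test_five_hour_run_counts_nothing(self):
        temps = np.full(48, 20.0)
        temps[10:15] = 5.0
        assert ts.cold_exposure_days(hourly_series(temps), 9.0) == 0

    def test_below_is_strict(self):
        temps = np.full(24, 9.0)  # exactly at threshold: not below
        assert ts.cold_exposure_days(hourly_series(temps), 9.0) == 0
        assert ts.cold_exposure_days(hourly_series(temps), 9.01) == 1

    def test_gappy_series_rejected(self):
        idx = pd.date_range("2002-01-01", periods=24, freq="2h")
        with pytest.raises(ContiguityError):
            ts.cold_exposure_days(pd.Series(5.0, index=idx), 9.0)

    def test_matches_brute_force_oracle_on_random_series(self):
        rng = np.random.default_rng(101)
        for _ in range(300):
            n_days = int(rng.integers(2, 10))
            temps = rng.normal(9.0, 6.0, n_days * 24)
            thr = float(rng.uniform(3.0, 12.0))
            run = int(rng.integers(1, 9))
            assert ts.cold_exposure_days(
                hourly_series(temps), thr, run
            ) == brute_force_cold_days(temps, thr, run)

    @given(
        temps=st.lists(st.floats(-5, 20), min_size=24, max_size=96),
        thr=st.floats(0, 15),
    )
    @settings(max_examples=60, deadline=None)
    def test_run_day_count_equals_oracle(self, temps, thr):
        temps = temps[: len(temps) // 24 * 24]
        day_idx = np.repeat(np.arange(len(temps) // 24), 24)
        assert run_day_count(
            np.asarray(temps) < thr, day_idx, 6
        ) == brute_force_cold_days(temps, thr, 6)


def make_hourly_day(temps, date=dt.date(2002, 1, 15), lat=29.68):
    solar = ts.solar_times(lat, date)
    return HourlyDay(date=date, temps=tuple(float(t) for t in temps), solar=solar)


def day_with_daylight_temps(values, fill=0.0, **kw):
    """HourlyDay whose daylight hours take ``values`` (padded with the
    last value), all other hours ``fill``."""
    day = make_hourly_day([fill] * 24, **kw)
    temps = np.full(24, fill)
    hours = day.solar.daylight_hours()
    vals = list(values) + [values[-1]] * (len(hours) - len(values))
    temps[hours] = vals[: len(hours)]
    return make_hourly_day(temps, **kw)


class TestActiveHours:
    def test_all_daylight_below_window_is_zero(self):
        day = day_with_daylight_temps([10.0])
        assert ts.active_hours(day, ts.ActivityConfig()) == 0

    def test_counts_only_in_window_daylight_hours(self):
        day = day_with_daylight_temps([25.0, 30.0, 35.0, 40.0, 10.0])
        assert ts.active_hours(day, ts.ActivityConfig()) == 4

    def test_saturates_at_daylight_count(self):
        day = day_with_daylight_temps([30.0])
        n_daylight = len(day.solar.daylight_hours())
        assert ts.active_hours(day, ts.ActivityConfig()) == n_daylight

    def test_window_bounds_inclusive(self):
        cfg = ts.ActivityConfig(pref_low=21.9, pref_high=40.6)
        day = day_with_daylight_temps([21.9, 40.6, 21.89, 40.61])
        assert ts.active_hours(day, cfg) == 2

    @given(
        widen=st.floats(0.0, 10.0),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=40, deadline=None)
    def test_widening_window_never_decreases_count(self, widen, seed):
        rng = np.random.default_rng(seed)
        day = make_hourly_day(rng.uniform(0, 45, 24))
        base = ts.ActivityConfig(pref_low=21.9, pref_high=40.6)
        wide = ts.ActivityConfig(pref_low=21.9 - widen, pref_high=40.6 + widen)
        assert ts.active_hours(day, wide) >= ts.active_hours(day, base)


class TestPctDaylightActive:
    def test_reported_average_row(self):
        # 4.55 active hours of 11 available daylight hours -> 41.36%
        assert ts.pct_daylight_active(4.55, 11) == pytest.approx(41.36, abs=0.005)

    @pytest.mark.parametrize("hours,expected", [(0.0, 0.0), (11.0, 100.0)])
    def test_extremes(self, hours, expected):
        assert ts.pct_daylight_active(hours, 11) == pytest.approx(expected)

    def test_zero_daylight_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ts.pct_daylight_active(1.0, 0.0)


class TestPerformanceMetrics:
    def test_all_hours_at_optimum_give_100pct(self, parabola_curve):
        day = day_with_daylight_temps([parabola_curve.argmax_T])
        assert ts.mean_performance_pct([day], parabola_curve) == pytest.approx(100.0)
        assert ts.frac_hours_ge80([day], parabola_curve) == 1.0

    def test_all_hours_at_anchor_give_0pct(self, parabola_curve):
        day = day_with_daylight_temps([PARABOLA_LOW], fill=PARABOLA_LOW)
        assert ts.mean_performance_pct([day], parabola_curve) == 0.0
        assert ts.frac_hours_ge80([day], parabola_curve) == 0.0

    def test_mixed_day_matches_hand_average(self, parabola_curve):
        temps = [15.0, 20.0, 25.0, 30.0, 35.0]
        day = day_with_daylight_temps(temps, fill=temps[-1])
        used = np.asarray(day.temps)[day.solar.daylight_hours()]
        expected = float(np.mean(parabola_curve.performance_percent(used)))
        assert ts.mean_performance_pct([day], parabola_curve) == pytest.approx(
            expected, abs=1e-6
        )

    def test_half_half_day_gives_half_fraction(self, parabola_curve):
        mid = parabola_curve.argmax_T
        n = len(make_hourly_day([0] * 24).solar.daylight_hours())
        half = n // 2
        vals = [mid] * half + [PARABOLA_LOW] * (n - half)
        day = day_with_daylight_temps(vals, fill=PARABOLA_LOW)
        assert ts.frac_hours_ge80([day], parabola_curve) == pytest.approx(half / n)

    def test_metrics_invariant_to_hour_ordering(self, parabola_curve):
        rng = np.random.default_rng(3)
        temps = rng.uniform(10, 39, 24)
        day = make_hourly_day(temps)
        hours = day.solar.daylight_hours()
        shuffled = temps.copy()
        shuffled[hours] = temps[hours][rng.permutation(len(hours))]
        day2 = make_hourly_day(shuffled)
        assert ts.mean_performance_pct([day], parabola_curve) == pytest.approx(
            ts.mean_performance_pct([day2], parabola_curve)
        )
        assert ts.frac_hours_ge80([day], parabola_curve) == ts.frac_hours_ge80(
            [day2], parabola_curve
        )


class TestMinMaxNormalize:
    def test_hand_computed(self):
        assert np.allclose(ts.minmax_normalize([2, 4, 6]), [0, 0.5, 1])

    def test_idempotent_on_unit_range(self):
        vals = np.array([0.0, 0.25, 1.0])
        assert np.allclose(ts.minmax_normalize(vals), vals)

    @given(
        shift=st.floats(-100, 100),
        scale=st.floats(0.01, 100),
    )
    @settings(max_examples=40, deadline=None)
    def test_affine_invariance(self, shift, scale):
        vals = np.array([1.0, 3.0, 7.0, 2.0])
        assert np.allclose(
            ts.minmax_normalize(vals * scale + shift),
            ts.minmax_normalize(vals),
            atol=1e-9,
        )

    def test_nan_propagates(self):
        out = ts.minmax_normalize([1.0, np.nan, 3.0])
        assert np.isnan(out[1]) and out[0] == 0.0 and out[2] == 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateRangeError):
            ts.minmax_normalize([5.0, 5.0, 5.0])


class TestSeasonMetrics:
    def test_flat_warm_season(self, parabola_curve):
        days = [
            make_hourly_day([30.0] * 24, date=dt.date(2002, 1, 10 + i))
            for i in range(3)
        ]
        m = ts.season_metrics(days, parabola_curve)
        assert all(v == 0 for v in m.days_below.values())
        n_daylight = len(days[0].solar.daylight_hours())
        assert m.active_hours_per_day == n_daylight
        assert m.pct_daylight_active == pytest.approx(100.0 * n_daylight / 11)
        assert m.mean_performance_pct == pytest.approx(
            float(parabola_curve.performance_percent(30.0))
        )

    def test_threshold_monotonicity(self, parabola_curve):
        rng = np.random.default_rng(8)
        days = [
            make_hourly_day(rng.normal(8, 6, 24), date=dt.date(2002, 1, 5 + i))
            for i in range(10)
        ]
        m = ts.season_metrics(days, parabola_curve)
        assert m.days_below[3.0] <= m.days_below[6.0] <= m.days_below[9.0]
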