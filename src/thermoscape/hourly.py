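"""Hourly temperature reconstruction from daily extremes.

Daily-grid climate products report only the daily minimum and maximum
temperature, but cold-exposure runs and activity windows are hourly
quantities. This module reconstructs 24 instantaneous hourly
temperatures per cell-day with the classic day/night decomposition used
in chill-accumulation modelling:

* **Daytime** (sunrise to sunset): temperature follows a sine rising
  from Tmin at sunrise, with the sine's half-period stretched 4 h past
  the daylength so the maximum falls in mid-afternoon rather than solar
  noon:  ``T(h) = Tmin + (Tmax - Tmin) * sin(pi * (h - sunrise) /
  (daylength + 4))``.
* **Nighttime** (sunset to next sunrise): temperature decays
  logarithmically from the sunset temperature toward the next morning's
  Tmin:  ``T(h) = Ts - (Ts - Tmin_next) * ln(h - sunset) / ln(night
  length)``, with the log argument floored at 1 so the first post-sunset
  hour equals the sunset temperature.

Hours before sunrise continue the previous night's decay toward the
current day's Tmin; the series is therefore continuous at sunset and
approximately continuous at sunrise. ``temps[h]`` is the instantaneous
temperature at local solar clock hour h (0–23).

Sunrise and sunset come from standard solar declination / hour-angle
geometry in local solar time; no atmospheric refraction or radiative
microclimate correction is applied.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

from .errors import SequencingError, UnsupportedLatitudeError

SINE_STRETCH_H = 4.0
"""Hours by which the daytime sine half-period exceeds the daylength."""


@dataclass(frozen=True)
class DayWeather:
    """Daily temperature extremes for one cell-day."""

    date: dt.date
    tmin: float
    tmax: float

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise ValueError(f"tmax < tmin on {self.date}")


@dataclass(frozen=True)
class SolarDay:
    """Sunrise/sunset (decimal local solar hours) for one date/latitude."""

    date: dt.date
    latitude: float
    sunrise: float
    sunset: float

    @property
    def daylength(self) -> float:
        return self.sunset - self.sunrise

    def daylight_hours(self) -> np.ndarray:
        """Integer clock hours h with sunrise <= h <= sunset."""
        return np.arange(int(np.ceil(self.sunrise)), int(np.floor(self.sunset)) + 1)


@dataclass(frozen=True)
class HourlyDay:
    """24 reconstructed hourly temperatures plus solar metadata."""

    date: dt.date
    temps: tuple[float, ...]
    solar: SolarDay

    def __post_init__(self) -> None:
        if len(self.temps) != 24:
            raise ValueError("need exactly 24 hourly temperatures")


def solar_declination(date: dt.date) -> float:
    """Solar declination (radians) for a calendar date.

    Uses the standard first-order Fourier approximation
    ``delta = -23.44° * cos(2*pi*(N+10)/365.24)`` with N the day of year;
    accurate to ~0.5°, ample for sunrise times on a climate grid.
    """
    n = date.timetuple().tm_yday
    return np.deg2rad(-23.44) * np.cos(2.0 * np.pi * (n + 10) / 365.24)


def solar_times(latitude: float, date: dt.date) -> SolarDay:
    """Sunrise and sunset (local solar time) from declination/hour-angle.

    ``cos(H) = -tan(lat) * tan(declination)`` gives the sunrise hour
    angle H; sunrise = 12 - H/15°, sunset = 12 + H/15°.

    Raises
    ------
    UnsupportedLatitudeError
        For |latitude| >= 66.5° (no polar day/night handling).
    """
    if abs(latitude) >= 66.5:
        raise UnsupportedLatitudeError(f"latitude {latitude} within polar circle")
    decl = solar_declination(date)
    cos_h = -np.tan(np.deg2rad(latitude)) * np.tan(decl)
    h_deg = np.rad2deg(np.arccos(np.clip(cos_h, -1.0, 1.0)))
    half = h_deg / 15.0
    return SolarDay(date=date, latitude=float(latitude),
                    sunrise=float(12.0 - half), sunset=float(12.0 + half))


def _daytime(h, tmin, tmax, sunrise, daylength):
    return tmin + (tmax - tmin) * np.sin(
        np.pi * (h - sunrise) / (daylength + SINE_STRETCH_H)
    )


def _sunset_temp(tmin, tmax, daylength):
    return _daytime(daylength, tmin, tmax, 0.0, daylength)


def _night(h_after_sunset, t_sunset, tmin_next, night_length):
    """Log decay from the sunset temperature toward the next Tmin."""
    t = np.maximum(np.asarray(h_after_sunset, dtype=float), 1.0)
    return t_sunset - (t_sunset - tmin_next) * np.log(t) / np.log(night_length)


def hourly_temperatures(
    prev: DayWeather, today: DayWeather, next_: DayWeather, solar: SolarDay
) -> HourlyDay:
    """Reconstruct the 24 hourly temperatures of ``today``.

    ``prev`` and ``next_`` supply the adjacent days' extremes for the
    night segments that cross midnight; at a season boundary pass the
    day itself (its own Tmin stands in for the missing neighbour).

    Raises
    ------
    SequencingError
        If prev/today/next dates are not consecutive (same-date
        sentinels for season boundaries are allowed).
    """
    one = dt.timedelta(days=1)
    if prev.date not in (today.date - one, today.date):
        raise SequencingError("prev day must precede today")
    if next_.date not in (today.date + one, today.date):
        raise SequencingError("next day must follow today")

    hours = np.arange(24.0)
    temps = np.empty(24)
    night_len = 24.0 - solar.daylength

    day_mask = (hours >= solar.sunrise) & (hours <= solar.sunset)
    temps[day_mask] = _daytime(
        hours[day_mask], today.tmin, today.tmax, solar.sunrise, solar.daylength
    )

    # after sunset: decay from today's sunset temperature to next.tmin
    evening = hours > solar.sunset
    ts_today = _sunset_temp(today.tmin, today.tmax, solar.daylength)
    temps[evening] = _night(hours[evening] - solar.sunset, ts_today,
                            next_.tmin, night_len)

    # before sunrise: previous night's decay toward today's tmin
    morning = hours < solar.sunrise
    ts_prev = _sunset_temp(prev.tmin, prev.tmax, solar.daylength)
    temps[morning] = _night(hours[morning] + 24.0 - solar.sunset, ts_prev,
                            today.tmin, night_len)

    return HourlyDay(date=today.date, temps=tuple(float(t) for t in temps),
                     solar=solar)


def reconstruct_series(
    days: list[DayWeather], latitude: float
) -> list[HourlyDay]:
    """Hourly reconstruction over a run of consecutive days.

    The first and last day reuse their own Tmin for the missing
    neighbour. Dates must be consecutive.

    Deterministic: identical inputs give bit-identical outputs.
    """
    for a, b in zip(days, days[1:]):
        if b.date - a.date != dt.timedelta(days=1):
            raise SequencingError(f"dates {a.date} and {b.date} not consecutive")
    out = []
    for i, today in enumerate(days):
        prev = days[i - 1] if i > 0 else today
        next_ = days[i + 1] if i + 1 < len(days) else today
        solar = solar_times(latitude, today.date)
        out.append(hourly_temperatures(prev, today, next_, solar))
    return out


def reconstruct_season_array(
    tmin: np.ndarray, tmax: np.ndarray, sunrise: np.ndarray, sunset: np.ndarray
) -> np.ndarray:
    """Vectorized reconstruction for one pixel-season.

    Parameters are per-day arrays of shape (n_days,); returns an
    (n_days, 24) array identical to stacking :func:`hourly_temperatures`
    over the season with boundary days reusing their own Tmin.
    """
    n = len(tmin)
    hours = np.arange(24.0)[None, :]
    sr = sunrise[:, None]
    ss = sunset[:, None]
    daylen = ss - sr
    night_len = 24.0 - daylen

    tmin_d = tmin[:, None]
    tmax_d = tmax[:, None]
    tmin_next = np.concatenate([tmin[1:], tmin[-1:]])[:, None]
    tmin_prev = np.concatenate([tmin[:1], tmin[:-1]])[:, None]
    tmax_prev = np.concatenate([tmax[:1], tmax[:-1]])[:, None]
    ts_today = tmin_d + (tmax_d - tmin_d) * np.sin(
        np.pi * daylen / (daylen + SINE_STRETCH_H)
    )
    # pre-dawn decay is evaluated with today's solar times (each day is
    # reconstructed against its own SolarDay), so the previous evening's
    # sunset temperature uses prev extremes but today's daylength
    ts_prev = tmin_prev + (tmax_prev - tmin_prev) * np.sin(
        np.pi * daylen / (daylen + SINE_STRETCH_H)
    )

    day = tmin_d + (tmax_d - tmin_d) * np.sin(
        np.pi * (hours - sr) / (daylen + SINE_STRETCH_H)
    )
    evening = ts_today - (ts_today - tmin_next) * (
        np.log(np.maximum(hours - ss, 1.0)) / np.log(night_len)
    )
    morning = ts_prev - (ts_prev - tmin_d) * (
        np.log(np.maximum(hours + 24.0 - ss, 1.0)) / np.log(night_len)
    )

    out = np.where(hours < sr, morning, np.where(hours > ss, evening, day))
    assert out.shape == (n, 24)
    return out
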