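"""Synthetic inputs with known ground truth.

Every stage of the pipeline is testable without external downloads:

* :func:`simulate_weather` emulates a PRISM-like daily Tmin/Tmax stack
  on a regular lat/lon grid — a latitudinal temperature gradient, a
  seasonal sinusoid, lag-1 autocorrelated (AR(1)) daily anomalies shared
  between a day's Tmin and Tmax, and a per-day diurnal range.
* :func:`simulate_sprint_data`, :func:`simulate_preference_series` and
  :func:`simulate_tolerance` emulate the trait trials: segment times
  back-computed from a known left-skewed thermal performance curve plus
  velocity noise, AR(1) body-temperature wander around a preferred
  target at 10 s cadence, and normally distributed critical limits with
  CTgape > CTmin enforced by redraw.
* :func:`simulate_presences` samples presence points from grid cells
  that satisfy a cold-exposure rule, mimicking localities where
  populations could establish.

All generators are reproducible: the same seed gives identical output.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .errors import InfeasibleRuleError
from .landscape import PresenceSet
from .traits import (
    PreferenceSeries,
    SprintTrial,
    ToleranceRecord,
)


@dataclass(frozen=True)
class WeatherSimConfig:
    """Parameters of the synthetic daily-weather generator.

    Defaults emulate a Florida-like peninsula in winter: annual-mean
    ~25 °C at the southern edge, ~1.7 °C cooler per degree of latitude
    (the steep winter lapse of the Florida peninsula), a ±5 °C seasonal
    cycle peaking in mid-summer, strongly autocorrelated day-to-day
    anomalies (cold snaps persist for days) and a 10 °C mean diurnal
    range — January then spans roughly Tmin 15/Tmax 25 °C in the south
    to Tmin 5/Tmax 15 °C in the north, as the real peninsula does.
    """

    nrow: int = 20
    ncol: int = 20
    lat_min: float = 25.0
    lat_max: float = 31.0
    lon_min: float = -83.0
    lon_max: float = -80.0
    start: dt.date = dt.date(2001, 12, 1)
    end: dt.date = dt.date(2002, 3, 1)
    base_mean_c: float = 25.0
    lapse_c_per_deg: float = 1.7
    seasonal_amplitude_c: float = 5.0
    diurnal_range_mean_c: float = 10.0
    diurnal_range_sd_c: float = 3.0
    ar1_coef: float = 0.7
    ar1_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must be in [0, 1)")
        if self.diurnal_range_mean_c <= 0:
            raise ValueError("diurnal range must be positive")


@dataclass(frozen=True)
class TraitSimConfig:
    """Parameters of the synthetic trait-trial generator.

    The true thermal performance curve is a left-skewed beta-type
    function zero at ``t_low``/``t_high`` and peaking at ``t_opt`` —
    the standard shape for ectotherm locomotor performance. Defaults
    place the limits at the measured tolerance means (9.9 and 39.2 °C)
    and the preferred target near the observed 32.8 °C.
    """

    peak_velocity: float = 1.0
    t_opt: float = 30.0
    t_low: float = 9.9
    t_high: float = 39.2
    shape_exponent: float = 2.0
    noise_sd: float = 0.05
    n_individuals: int = 10
    test_temperatures: tuple[float, ...] = (15.0, 20.0, 25.0, 30.0, 35.0)
    pref_target_c: float = 32.8
    pref_wander_sd_c: float = 2.0
    pref_ar1_coef: float = 0.9
    ctmin_mean: float = 9.9
    ctmin_sd: float = 2.0
    ctgape_mean: float = 39.2
    ctgape_sd: float = 1.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.t_low < self.t_opt < self.t_high:
            raise ValueError("zero endpoints must bracket the optimum")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")

    def true_velocity(self, t) -> np.ndarray:
        """The generator's ground-truth performance curve (m/s)."""
        t = np.asarray(t, dtype=float)
        a = self.shape_exponent
        b = a * (self.t_high - self.t_opt) / (self.t_opt - self.t_low)
        with np.errstate(invalid="ignore"):
            rise = ((t - self.t_low) / (self.t_opt - self.t_low)) ** a
            fall = ((self.t_high - t) / (self.t_high - self.t_opt)) ** b
            v = self.peak_velocity * rise * fall
        return np.where((t <= self.t_low) | (t >= self.t_high), 0.0, v)


def simulate_weather(cfg: WeatherSimConfig) -> xr.Dataset:
    """Daily Tmin/Tmax stack on (time, lat, lon).

    ``Tmean(cell, day) = base - lapse * (lat - lat_south) + seasonal
    sinusoid + AR(1) anomaly``; Tmin/Tmax are Tmean -/+ half the day's
    diurnal range (drawn per cell-day, floored at 0.5 °C). One anomaly
    per cell-day is shared by Tmin and Tmax so day-to-day
    autocorrelation — which the consecutive-hour cold statistic depends
    on — is preserved.
    """
    rng = np.random.default_rng(cfg.seed)
    dates = pd.date_range(cfg.start, cfg.end, freq="D")
    lats = np.linspace(cfg.lat_min, cfg.lat_max, cfg.nrow)
    lons = np.linspace(cfg.lon_min, cfg.lon_max, cfg.ncol)
    nd = len(dates)

    doy = dates.dayofyear.to_numpy()
    seasonal = cfg.seasonal_amplitude_c * np.cos(2 * np.pi * (doy - 196) / 365.25)

    anom = np.zeros((nd, cfg.nrow, cfg.ncol))
    innov_sd = cfg.ar1_sd * np.sqrt(1 - cfg.ar1_coef**2)
    anom[0] = rng.normal(0.0, cfg.ar1_sd, (cfg.nrow, cfg.ncol))
    for k in range(1, nd):
        anom[k] = cfg.ar1_coef * anom[k - 1] + rng.normal(
            0.0, innov_sd, (cfg.nrow, cfg.ncol)
        )

    tmean = (
        cfg.base_mean_c
        - cfg.lapse_c_per_deg * (lats - cfg.lat_min)[None, :, None]
        + seasonal[:, None, None]
        + anom
    )
    half_range = np.maximum(
        rng.normal(cfg.diurnal_range_mean_c, cfg.diurnal_range_sd_c,
                   (nd, cfg.nrow, cfg.ncol)),
        0.5,
    ) / 2.0

    return xr.Dataset(
        {
            "tmin": (("time", "lat", "lon"), tmean - half_range),
            "tmax": (("time", "lat", "lon"), tmean + half_range),
        },
        coords={"time": dates, "lat": lats, "lon": lons},
        attrs={"generator": "thermoscape.synth.simulate_weather",
               "seed": cfg.seed},
    )


def simulate_sprint_data(cfg: TraitSimConfig) -> list[SprintTrial]:
    """Sprint trials per individual × test temperature.

    Segment times are 0.25 m divided by the true-curve velocity plus
    Gaussian noise (floored at a small positive velocity), two laps of
    six segments per trial.
    """
    rng = np.random.default_rng(cfg.seed)
    trials = []
    for i in range(cfg.n_individuals):
        ind = f"sim{i:02d}"
        for t in cfg.test_temperatures:
            v_true = float(cfg.true_velocity(t))
            v = np.maximum(rng.normal(v_true, cfg.noise_sd, 12), 0.02)
            trials.append(
                SprintTrial(
                    individual_id=ind,
                    test_temperature=float(t),
                    segment_times=tuple(0.25 / v),
                    valid=True,
                )
            )
    return trials


def simulate_preference_series(
    cfg: TraitSimConfig, duration_min: float = 65.0, cadence_s: float = 10.0
) -> list[PreferenceSeries]:
    """Body-temperature series per individual: AR(1) wander around the
    preferred target, 10 s cadence for 65 min, first 5 min flagged for
    discard."""
    rng = np.random.default_rng(cfg.seed + 1)
    n = int(duration_min * 60 / cadence_s)
    out = []
    innov_sd = cfg.pref_wander_sd_c * np.sqrt(1 - cfg.pref_ar1_coef**2)
    for i in range(cfg.n_individuals):
        x = np.empty(n)
        x[0] = rng.normal(cfg.pref_target_c, cfg.pref_wander_sd_c)
        for k in range(1, n):
            x[k] = cfg.pref_target_c + cfg.pref_ar1_coef * (
                x[k - 1] - cfg.pref_target_c
            ) + rng.normal(0.0, innov_sd)
        out.append(
            PreferenceSeries(
                individual_id=f"sim{i:02d}",
                timestamps=tuple(np.arange(n) * cadence_s),
                body_temps=tuple(x),
                discard_initial=5.0,
            )
        )
    return out


def simulate_tolerance(cfg: TraitSimConfig, season: str = "winter") -> list[ToleranceRecord]:
    """CTmin/CTgape per individual from the configured normals;
    CTgape > CTmin enforced by redraw."""
    rng = np.random.default_rng(cfg.seed + 2)
    out = []
    for i in range(cfg.n_individuals):
        while True:
            ctmin = rng.normal(cfg.ctmin_mean, cfg.ctmin_sd)
            ctgape = rng.normal(cfg.ctgape_mean, cfg.ctgape_sd)
            if ctgape > ctmin:
                break
        out.append(
            ToleranceRecord(
                individual_id=f"sim{i:02d}", season=season,
                ctmin=float(ctmin), ctgape=float(ctgape),
            )
        )
    return out


def simulate_presences(
    days_below: xr.DataArray, max_days_below: float, n_points: int, seed: int = 0
) -> PresenceSet:
    """Sample presence points from cells whose mean cold-exposure days
    do not exceed ``max_days_below``.

    Points are placed uniformly within qualifying cells (jittered around
    cell centres by less than half a cell so nearest-cell lookup
    recovers the sampled cell).
    """
    rng = np.random.default_rng(seed)
    ok = np.argwhere(days_below.values <= max_days_below)
    if len(ok) == 0:
        raise InfeasibleRuleError("no grid cell satisfies the presence rule")
    lats = days_below["lat"].values
    lons = days_below["lon"].values
    dlat = np.abs(np.diff(lats)).mean() if lats.size > 1 else 0.0
    dlon = np.abs(np.diff(lons)).mean() if lons.size > 1 else 0.0
    picks = ok[rng.integers(0, len(ok), n_points)]
    pts = []
    for r, c in picks:
        lat = lats[r] + rng.uniform(-0.45, 0.45) * dlat
        lon = lons[c] + rng.uniform(-0.45, 0.45) * dlon
        pts.append((float(lon), float(lat)))
    return PresenceSet(points=tuple(pts))
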