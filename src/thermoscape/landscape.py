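"""Landscape projection of exposure metrics over daily Tmin/Tmax grids.

For every pixel of a regular lat/lon daily-weather stack and every
winter season window (Dec 15 – Feb 15), the pipeline reconstructs
hourly temperatures, computes the three exposure models, averages the
per-season values across seasons, and emits one metric raster per
quantity plus min-max normalized variants of the activity and
performance models. Values at presence localities are then extracted
(nearest cell; duplicate points per cell collapsed) and summarized as
min / max / average per metric.

The in-memory grid container is an :class:`xarray.Dataset` with
``tmin``/``tmax`` variables on (time, lat, lon); metric rasters are
:class:`xarray.DataArray` on (lat, lon) carrying the input
georeference unchanged.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from . import exposure
from .errors import (
    AlignmentError,
    CoverageError,
    DegenerateRangeError,
    OutOfExtentError,
)
from .exposure import ActivityConfig, ColdExposureConfig
from .hourly import reconstruct_season_array, solar_times
from .performance import PerformanceCurve

METRIC_NAMES = (
    "days_below_9",
    "days_below_6",
    "days_below_3",
    "active_hours",
    "pct_daylight_active",
    "mean_performance_pct",
    "frac_hours_ge80",
)


@dataclass(frozen=True)
class SeasonWindow:
    """One winter window: Dec 15 of ``start_year`` to Feb 15 of the next
    year, inclusive."""

    start_year: int

    @property
    def start(self) -> dt.date:
        return dt.date(self.start_year, 12, 15)

    @property
    def end(self) -> dt.date:
        return dt.date(self.start_year + 1, 2, 15)

    @property
    def label(self) -> str:
        return str(self.start_year)

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")


def season_windows(first_start_year: int, last_start_year: int) -> list[SeasonWindow]:
    """One SeasonWindow per starting year, inclusive."""
    if first_start_year > last_start_year:
        raise ValueError("first_start_year must not exceed last_start_year")
    return [SeasonWindow(y) for y in range(first_start_year, last_start_year + 1)]


@dataclass(frozen=True)
class PresenceSet:
    """Presence localities; duplicates within one grid cell collapse."""

    points: tuple[tuple[float, float], ...]  # (lon, lat)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PresenceSet":
        return cls(points=tuple(zip(df["lon"].astype(float), df["lat"].astype(float))))

    def collapsed_cells(self, raster: xr.DataArray) -> list[tuple[int, int]]:
        """Distinct (row, col) cells containing >= 1 point, in first-seen
        order. Points are assigned to the cell whose centre is nearest."""
        lats = raster["lat"].values
        lons = raster["lon"].values
        cells: list[tuple[int, int]] = []
        for lon, lat in self.points:
            if not (
                _within(lat, lats) and _within(lon, lons)
            ):
                raise OutOfExtentError(f"point ({lon}, {lat}) outside raster bounds")
            cell = (int(np.abs(lats - lat).argmin()), int(np.abs(lons - lon).argmin()))
            if cell not in cells:
                cells.append(cell)
        return cells


def _within(x: float, centers: np.ndarray) -> bool:
    half = np.abs(np.diff(centers)).mean() / 2 if centers.size > 1 else np.inf
    return centers.min() - half <= x <= centers.max() + half


@dataclass(frozen=True)
class ExtractionSummary:
    """Min / max / average of each metric over collapsed presence cells."""

    n_cells: int
    stats: dict[str, tuple[float, float, float]]  # metric -> (min, max, mean)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stats, index=["min", "max", "average"])
        df.index.name = "statistic"
        return df


def _check_stack(stack: xr.Dataset) -> None:
    for var in ("tmin", "tmax"):
        if var not in stack:
            raise AlignmentError(f"stack missing variable {var!r}")
    if not np.array_equal(
        stack["tmin"]["lat"].values, stack["tmax"]["lat"].values
    ) or not np.array_equal(stack["tmin"]["lon"].values, stack["tmax"]["lon"].values):
        raise AlignmentError("tmin and tmax grids are misaligned")


def project_metrics(
    stack: xr.Dataset,
    windows: list[SeasonWindow],
    curve: PerformanceCurve,
    cold_cfg: ColdExposureConfig = ColdExposureConfig(),
    act_cfg: ActivityConfig = ActivityConfig(),
) -> xr.Dataset:
    """Project all exposure metrics over the grid, averaged across seasons.

    Returns a Dataset of metric rasters on the input (lat, lon)
    georeference: per-threshold cold-exposure day counts, mean active
    hours, percent of daylight active, mean performance %, the >= 80%
    performance fraction, and min-max normalized activity and
    performance rasters.
    """
    _check_stack(stack)
    times = pd.DatetimeIndex(stack["time"].values)
    lats = stack["lat"].values
    lons = stack["lon"].values
    nlat, nlon = len(lats), len(lons)

    thr_names = {thr: f"days_below_{_fmt(thr)}" for thr in cold_cfg.thresholds}
    acc: dict[str, np.ndarray] = {
        name: np.zeros((nlat, nlon)) for name in thr_names.values()
    }
    for name in ("active_hours", "pct_daylight_active",
                 "mean_performance_pct", "frac_hours_ge80"):
        acc[name] = np.zeros((nlat, nlon))

    for window in windows:
        dates = window.dates()
        missing = dates.difference(times)
        if len(missing):
            raise CoverageError(
                f"stack missing {len(missing)} dates for window {window.label}"
            )
        sel = stack.sel(time=dates)
        tmin = sel["tmin"].transpose("time", "lat", "lon").values
        tmax = sel["tmax"].transpose("time", "lat", "lon").values
        ndays = len(dates)
        day_index = np.repeat(np.arange(ndays), 24)

        # solar geometry varies with latitude row and date only
        solar = [
            [solar_times(float(lat), d.date()) for d in dates] for lat in lats
        ]
        sunrise = np.array([[s.sunrise for s in row] for row in solar])  # (nlat, nd)
        sunset = np.array([[s.sunset for s in row] for row in solar])
        day_masks = [
            np.stack([_hour_mask(s) for s in row]) for row in solar
        ]  # per lat row: (ndays, 24) bool

        for i in range(nlat):
            mask = day_masks[i]
            n_daylight = mask.sum(axis=1).astype(float)  # hours per day
            for j in range(nlon):
                hourly = reconstruct_season_array(
                    tmin[:, i, j], tmax[:, i, j], sunrise[i], sunset[i]
                )
                flat = hourly.ravel()
                for thr, name in thr_names.items():
                    acc[name][i, j] += exposure.run_day_count(
                        flat < thr, day_index, cold_cfg.min_run_hours
                    )
                in_window = (hourly >= act_cfg.pref_low) & (hourly <= act_cfg.pref_high)
                active_per_day = (in_window & mask).sum(axis=1)
                mean_active = active_per_day.mean()
                acc["active_hours"][i, j] += mean_active
                denom = (
                    exposure.FIXED_DAYLIGHT_HOURS
                    if act_cfg.daylight_mode == "fixed-11"
                    else n_daylight.mean()
                )
                acc["pct_daylight_active"][i, j] += 100.0 * mean_active / denom
                daylight_temps = hourly[mask]
                pct = curve.performance_percent(daylight_temps)
                acc["mean_performance_pct"][i, j] += pct.mean()
                acc["frac_hours_ge80"][i, j] += np.mean(pct >= 80.0)

    n = len(windows)
    coords = {"lat": lats, "lon": lons}
    out = xr.Dataset(
        {name: (("lat", "lon"), vals / n) for name, vals in acc.items()},
        coords=coords,
    )
    for norm_name, src in (
        ("active_hours_norm", "active_hours"),
        ("mean_performance_norm", "mean_performance_pct"),
    ):
        try:
            normed = exposure.minmax_normalize(out[src].values)
        except DegenerateRangeError:
            # a spatially constant metric has no meaningful relative scale
            normed = np.full((nlat, nlon), np.nan)
        out[norm_name] = (("lat", "lon"), normed)
    out.attrs["seasons"] = ",".join(w.label for w in windows)
    return out


def _fmt(thr: float) -> str:
    return str(int(thr)) if float(thr).is_integer() else str(thr).replace(".", "p")


def _hour_mask(solar_day) -> np.ndarray:
    hours = np.arange(24)
    return (hours >= solar_day.sunrise) & (hours <= solar_day.sunset)


def extract_at_presences(
    metrics: xr.Dataset, presences: PresenceSet
) -> ExtractionSummary:
    """Summarize metric rasters at presence localities.

    Each point maps to its nearest cell; points sharing a cell collapse
    to one before summarizing. Cells that are no-data (NaN) for a metric
    are excluded from that metric's summary.
    """
    first = metrics[list(metrics.data_vars)[0]]
    cells = presences.collapsed_cells(first)
    stats: dict[str, tuple[float, float, float]] = {}
    for name, raster in metrics.data_vars.items():
        vals = np.array([raster.values[r, c] for r, c in cells], dtype=float)
        ok = vals[np.isfinite(vals)]
        if ok.size == 0:
            stats[name] = (np.nan, np.nan, np.nan)
            continue
        stats[name] = (float(ok.min()), float(ok.max()), float(ok.mean()))
    return ExtractionSummary(n_cells=len(cells), stats=stats)
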