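"""Physiological exposure metrics on hourly temperature series.

Three exposure models translate reconstructed hourly temperatures into
biologically interpretable winter metrics:

1. **Cold exposure** — days touched by a run of at least
   ``min_run_hours`` (default 6) consecutive hours strictly below a
   threshold. Default thresholds {9, 6, 3} °C correspond to ~1 °C below
   the population mean CTmin, the lowest individual CTmin, and a value
   below anything the animals experienced. The 6 h persistence rule
   filters out brief dips (passing fronts) that body thermal inertia
   would buffer.
2. **Activity window** — daylight hours whose ambient temperature lies
   within the range of body temperatures the animals voluntarily
   selected in a preference gradient (defaults 21.9–40.6 °C).
3. **Predicted performance** — mean percentage-of-maximum sprint
   performance over daylight hours, and the fraction of daylight hours
   at or above 80% of maximum.

Min-max normalization rescales any metric so its minimum maps to 0 and
its maximum to 1, making differently-scaled models comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContiguityError, DegenerateRangeError
from .hourly import HourlyDay
from .performance import PerformanceCurve

DEFAULT_THRESHOLDS_C = (9.0, 6.0, 3.0)
DEFAULT_MIN_RUN_HOURS = 6
FIXED_DAYLIGHT_HOURS = 11.0
"""Available daylight hours per winter day in fixed-denominator mode."""


@dataclass(frozen=True)
class ColdExposureConfig:
    """Thresholds (°C) and the consecutive-hour persistence rule."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS_C
    min_run_hours: int = DEFAULT_MIN_RUN_HOURS

    def __post_init__(self) -> None:
        if self.min_run_hours < 1:
            raise ValueError("min_run_hours must be >= 1")
        if not all(np.isfinite(self.thresholds)):
            raise ValueError("thresholds must be finite")


@dataclass(frozen=True)
class ActivityConfig:
    """Preferred-temperature window and the daylight-denominator mode.

    ``daylight_mode`` is ``"fixed-11"`` (Table-style reporting with 11
    available daylight hours) or ``"astronomical"`` (per-day solar
    daylength as the denominator).
    """

    pref_low: float = 21.9
    pref_high: float = 40.6
    daylight_mode: str = "fixed-11"

    def __post_init__(self) -> None:
        if self.pref_low >= self.pref_high:
            raise ValueError("pref_low must be below pref_high")
        if self.daylight_mode not in ("fixed-11", "astronomical"):
            raise ValueError("daylight_mode must be 'fixed-11' or 'astronomical'")


@dataclass(frozen=True)
class SeasonMetrics:
    """Per-season exposure metrics for one pixel."""

    days_below: dict[float, int]
    active_hours_per_day: float
    pct_daylight_active: float
    mean_performance_pct: float
    frac_hours_ge80: float


def cold_exposure_days(
    hourly: pd.Series, threshold: float, min_run_hours: int = DEFAULT_MIN_RUN_HOURS
) -> int:
    """Days touched by a sub-threshold run of >= ``min_run_hours`` hours.

    ``hourly`` is a temperature series indexed by a contiguous hourly
    DatetimeIndex covering one season. Runs of consecutive hours with
    temperature strictly below ``threshold`` are located on the full
    series — runs may cross midnight — and every calendar day containing
    at least one hour of a qualifying run is counted once.
    """
    if not isinstance(hourly.index, pd.DatetimeIndex):
        raise ContiguityError("hourly series must have a DatetimeIndex")
    deltas = np.diff(hourly.index.asi8)
    if len(deltas) and not (deltas == 3_600_000_000_000).all():
        raise ContiguityError("hourly series has gaps or irregular spacing")

    below = hourly.to_numpy() < threshold
    day_index = hourly.index.normalize().asi8 // 86_400_000_000_000
    return run_day_count(below, day_index, min_run_hours)


def run_day_count(
    below: np.ndarray, day_index: np.ndarray, min_run_hours: int
) -> int:
    """Count distinct days touched by a below-threshold run of
    >= ``min_run_hours`` consecutive hours.

    ``below`` is a boolean mask over a contiguous hourly series and
    ``day_index`` labels each hour with its calendar day; a run crossing
    midnight counts for every day it touches.
    """
    below = np.asarray(below).astype(int)
    starts = np.diff(np.concatenate([[0], below])) == 1
    run_id = np.cumsum(starts) * below
    if not run_id.any():
        return 0
    lengths = np.bincount(run_id)
    counted: set = set()
    for rid in np.nonzero(lengths[1:] >= min_run_hours)[0] + 1:
        counted.update(np.asarray(day_index)[run_id == rid].tolist())
    return len(counted)


def active_hours(day: HourlyDay, cfg: ActivityConfig) -> int:
    """Count of daylight hours within the preferred-temperature window.

    Daylight hours are clock hours h with sunrise <= h <= sunset;
    membership in [pref_low, pref_high] is inclusive at both ends
    because the window ends are themselves recorded body temperatures.
    """
    temps = np.asarray(day.temps)[day.solar.daylight_hours()]
    return int(((temps >= cfg.pref_low) & (temps <= cfg.pref_high)).sum())


def pct_daylight_active(mean_active_hours: float, available_daylight: float) -> float:
    """Active hours as a percentage of available daylight hours."""
    if available_daylight <= 0:
        raise ZeroDivisionError("available_daylight must be positive")
    return 100.0 * mean_active_hours / available_daylight


def _daylight_temps(days: Sequence[HourlyDay]) -> np.ndarray:
    return np.concatenate(
        [np.asarray(d.temps)[d.solar.daylight_hours()] for d in days]
    )


def mean_performance_pct(days: Sequence[HourlyDay], curve: PerformanceCurve) -> float:
    """Mean predicted performance (% of maximum) over all daylight hours."""
    return float(np.mean(curve.performance_percent(_daylight_temps(days))))


def frac_hours_ge80(
    days: Sequence[HourlyDay], curve: PerformanceCurve, cutoff: float = 80.0
) -> float:
    """Fraction of daylight hours at or above ``cutoff``% of maximum
    performance."""
    pct = curve.performance_percent(_daylight_temps(days))
    return float(np.mean(pct >= cutoff))


def season_metrics(
    days: Sequence[HourlyDay],
    curve: PerformanceCurve,
    cold_cfg: ColdExposureConfig = ColdExposureConfig(),
    act_cfg: ActivityConfig = ActivityConfig(),
) -> SeasonMetrics:
    """All exposure metrics for one pixel-season of hourly days."""
    index = pd.DatetimeIndex(
        [pd.Timestamp(d.date) + pd.Timedelta(hours=h) for d in days for h in range(24)]
    )
    series = pd.Series(
        np.concatenate([np.asarray(d.temps) for d in days]), index=index
    )
    days_below = {
        thr: cold_exposure_days(series, thr, cold_cfg.min_run_hours)
        for thr in cold_cfg.thresholds
    }
    per_day_active = [active_hours(d, act_cfg) for d in days]
    mean_active = float(np.mean(per_day_active))
    if act_cfg.daylight_mode == "fixed-11":
        denom = FIXED_DAYLIGHT_HOURS
    else:
        denom = float(np.mean([len(d.solar.daylight_hours()) for d in days]))
    return SeasonMetrics(
        days_below=days_below,
        active_hours_per_day=mean_active,
        pct_daylight_active=pct_daylight_active(mean_active, denom),
        mean_performance_pct=mean_performance_pct(days, curve),
        frac_hours_ge80=frac_hours_ge80(days, curve),
    )


def minmax_normalize(values):
    """Affine rescale so the minimum maps to 0 and the maximum to 1.

    Accepts any array-like (NaNs propagate as missing); raises
    DegenerateRangeError when all finite values are equal.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2 or finite.min() == finite.max():
        raise DegenerateRangeError("need at least two distinct finite values")
    return (arr - finite.min()) / (finite.max() - finite.min())
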