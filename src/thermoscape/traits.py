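"""Thermal-trait metrics from raw trial measurements.

This module turns the three kinds of laboratory trial an ectotherm
thermal-biology study collects into the scalar metrics the landscape
projection consumes:

* **Sprint trials** — stopwatch times over fixed 0.25 m track segments at
  a set of test body temperatures; converted to per-segment velocities,
  of which only the individual's maximum per temperature is retained.
* **Q10 thermal sensitivity** — the factor by which sprint velocity
  changes per 10 °C of body temperature,
  ``Q10 = (v2 / v1) ** (10 / (T2 - T1))``,
  computed over adjacent 5 °C test intervals only (wider spans are
  discarded because the exponent then averages over unlike physiology).
* **Critical thermal limits** — CTmin (loss of righting response) and
  CTgape (sustained gaping, the heat-stress proxy for CTmax); thermal
  breadth is their difference.
* **Thermal preference** — cloacal temperature logged every 10 s for
  65 min in a thermal gradient, with the first 5 min discarded as arena
  acclimation; summarized as mean, binned mode, sample SD and range.
  The recorded range of voluntarily selected body temperatures later
  defines the activity window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    ExcludedTrialError,
    InsufficientDataError,
    InvalidMeasurementError,
    OrderingError,
    UndefinedIntervalError,
)

SEGMENT_LENGTH_M = 0.25
"""Length of one sprint-track segment in metres (six segments per lap)."""

TEST_TEMPERATURES = (15.0, 20.0, 25.0, 30.0, 35.0)
"""Body temperatures (°C) at which sprint performance is assayed."""

Q10_INTERVALS = ((15.0, 20.0), (20.0, 25.0), (25.0, 30.0), (30.0, 35.0))
"""The adjacent 5 °C intervals over which Q10 is defined."""


@dataclass(frozen=True)
class SprintTrial:
    """One sprint lap-set for one individual at one test temperature.

    ``segment_times`` are seconds per ordered 0.25 m segment, both laps
    concatenated. ``valid`` is False when the animal refused to move or
    was uncooperative; such trials are excluded from all downstream
    computation but kept in input files so the filtering is auditable.
    """

    individual_id: str
    test_temperature: float
    segment_times: tuple[float, ...]
    valid: bool = True
    season: str = ""


@dataclass(frozen=True)
class Q10Record:
    """Thermal sensitivity of one individual over one 5 °C interval."""

    individual_id: str
    interval: tuple[float, float]
    q10: float

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not np.isclose(hi - lo, 10.0 / 2):
            raise ValueError(f"Q10 interval must span 5 °C, got {self.interval}")
        if self.q10 <= 0:
            raise ValueError("q10 must be positive")


@dataclass(frozen=True)
class ToleranceRecord:
    """Critical thermal limits of one individual in one season.

    ``tbreadth`` is always ``ctgape - ctmin``; it is stored rather than
    recomputed so serialized records are self-contained.
    """

    individual_id: str
    season: str
    ctmin: float
    ctgape: float
    tbreadth: float = field(init=False)

    def __post_init__(self) -> None:
        if self.ctgape <= self.ctmin:
            raise OrderingError(
                f"CTgape ({self.ctgape}) must exceed CTmin ({self.ctmin})"
            )
        object.__setattr__(self, "tbreadth", self.ctgape - self.ctmin)


@dataclass(frozen=True)
class PreferenceSeries:
    """Body-temperature time series from one thermal-preference trial.

    Timestamps are seconds from trial start at a nominal 10 s cadence.
    Only samples at or after ``discard_initial`` minutes are analyzed.
    """

    individual_id: str
    timestamps: tuple[float, ...]
    body_temps: tuple[float, ...]
    discard_initial: float = 5.0
    season: str = ""

    def retained(self) -> np.ndarray:
        """Body temperatures after the initial discard window."""
        t = np.asarray(self.timestamps, dtype=float)
        x = np.asarray(self.body_temps, dtype=float)
        return x[t >= self.discard_initial * 60.0]


@dataclass(frozen=True)
class PreferenceSummary:
    """Mean, binned mode, sample SD and range of one preference trial."""

    mean: float
    mode: float
    sd: float
    temp_range: tuple[float, float]


@dataclass(frozen=True)
class TraitSummary:
    """Population-level thermal metrics that drive the projection models."""

    mean_ctmin: float
    lowest_ctmin: float
    mean_ctgape: float
    mean_tbreadth: float
    tpref_mean: float
    tpref_mode: float
    tpref_sd: float
    pref_range: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.pref_range
        if not (lo <= self.tpref_mean <= hi):
            raise ValueError("tpref_mean must lie within pref_range")
        if self.lowest_ctmin > self.mean_ctmin:
            raise ValueError("lowest_ctmin cannot exceed mean_ctmin")


def segment_velocities(trial: SprintTrial) -> tuple[np.ndarray, float]:
    """Per-segment sprint velocities (m/s) and the maximal segment speed.

    Velocity of each segment is the fixed 0.25 m segment length divided
    by the stopwatch time for that segment; the maximum is taken over
    every segment of both laps.

    Raises
    ------
    ExcludedTrialError
        If the trial is flagged invalid (uncooperative animal).
    InvalidMeasurementError
        If any segment time is missing or non-positive.
    """
    if not trial.valid:
        raise ExcludedTrialError(
            f"trial for {trial.individual_id} at {trial.test_temperature} °C "
            "is flagged invalid"
        )
    times = np.asarray(trial.segment_times, dtype=float)
    if times.size == 0 or np.any(~np.isfinite(times)) or np.any(times <= 0):
        raise InvalidMeasurementError("segment times must be finite and positive")
    velocities = SEGMENT_LENGTH_M / times
    return velocities, float(velocities.max())


def q10(v1: float, v2: float, t1: float, t2: float) -> float:
    """Thermal sensitivity coefficient ``(v2 / v1) ** (10 / (t2 - t1))``.

    A value of 2 means the rate doubles per 10 °C increase, 1 means
    thermal independence, 0.5 a halving per 10 °C.
    """
    if t1 == t2:
        raise UndefinedIntervalError("Q10 undefined over a zero-width interval")
    if v1 <= 0 or v2 <= 0:
        raise InvalidMeasurementError("velocities must be positive")
    return float((v2 / v1) ** (10.0 / (t2 - t1)))


def q10_intervals(
    max_velocities: Mapping[float, float], individual_id: str = ""
) -> list[Q10Record]:
    """Q10 records over every adjacent 5 °C interval with both endpoints.

    ``max_velocities`` maps test temperature (°C) to the individual's
    maximal segment velocity at that temperature. Intervals missing an
    endpoint silently yield no record — the discard rule for trials that
    would span wider than 5 °C.
    """
    records = []
    for lo, hi in Q10_INTERVALS:
        if lo in max_velocities and hi in max_velocities:
            records.append(
                Q10Record(
                    individual_id=individual_id,
                    interval=(lo, hi),
                    q10=q10(max_velocities[lo], max_velocities[hi], lo, hi),
                )
            )
    return records


def thermal_breadth(ctmin: float, ctgape: float) -> float:
    """Thermal breadth: CTgape minus CTmin (°C)."""
    if ctgape <= ctmin:
        raise OrderingError(f"CTgape ({ctgape}) must exceed CTmin ({ctmin})")
    return ctgape - ctmin


def preference_summary(
    series: PreferenceSeries, mode_bin: float = 0.1
) -> PreferenceSummary:
    """Summary statistics of one thermal-preference trial.

    Mean and SD (n−1 denominator) are over retained samples. The mode of
    the continuous series is the centre of the most populated bin of
    width ``mode_bin`` (default 0.1 °C, the logger resolution); ties
    break to the lowest bin for determinism.
    """
    x = series.retained()
    if x.size < 2:
        raise InsufficientDataError(
            "need at least 2 retained samples after the discard window"
        )
    # bin index k covers [k*mode_bin, (k+1)*mode_bin); the small epsilon
    # keeps values that are exact bin multiples in the bin they name
    # despite float division error
    k = np.floor(x / mode_bin + 1e-9).astype(int)
    counts = np.bincount(k - k.min())
    # bincount argmax returns the first maximal bin: ties break low
    mode = (k.min() + int(counts.argmax()) + 0.5) * mode_bin
    return PreferenceSummary(
        mean=float(x.mean()),
        mode=float(mode),
        sd=float(x.std(ddof=1)),
        temp_range=(float(x.min()), float(x.max())),
    )


def summarize_traits(
    tolerance: Iterable[ToleranceRecord],
    preference: Sequence[PreferenceSeries],
    mode_bin: float = 0.1,
) -> TraitSummary:
    """Population TraitSummary from tolerance records and preference trials.

    Tolerance means are plain averages over records (individual × season);
    preference statistics are per-trial summaries averaged across trials,
    and ``pref_range`` spans the extreme body temperatures recorded in
    any trial — the end-points that define the activity window.
    """
    tol = list(tolerance)
    if not tol or not preference:
        raise InsufficientDataError("need tolerance records and preference trials")
    summaries = [preference_summary(s, mode_bin=mode_bin) for s in preference]
    return TraitSummary(
        mean_ctmin=float(np.mean([r.ctmin for r in tol])),
        lowest_ctmin=float(min(r.ctmin for r in tol)),
        mean_ctgape=float(np.mean([r.ctgape for r in tol])),
        mean_tbreadth=float(np.mean([r.tbreadth for r in tol])),
        tpref_mean=float(np.mean([s.mean for s in summaries])),
        tpref_mode=float(np.mean([s.mode for s in summaries])),
        tpref_sd=float(np.mean([s.sd for s in summaries])),
        pref_range=(
            float(min(s.temp_range[0] for s in summaries)),
            float(max(s.temp_range[1] for s in summaries)),
        ),
    )


def max_velocities_by_temperature(
    trials: Iterable[SprintTrial],
) -> dict[str, dict[float, float]]:
    """Per-individual map of test temperature → maximal segment velocity.

    Invalid trials are skipped (the auditable exclusion rule); when an
    individual has several valid trials at a temperature the overall
    maximum across trials is kept.
    """
    out: dict[str, dict[float, float]] = {}
    for trial in trials:
        if not trial.valid:
            continue
        _, vmax = segment_velocities(trial)
        per = out.setdefault(trial.individual_id, {})
        t = float(trial.test_temperature)
        per[t] = max(per.get(t, 0.0), vmax)
    return out
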