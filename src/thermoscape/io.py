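"""File formats: trait CSVs, daily-weather NetCDF stacks, presence CSVs.

Sprint trials travel in long format (one row per segment), so the
uncooperative-trial exclusion stays auditable in the file; preference
series are long (one row per logged sample); tolerance records are one
row per individual × season. Weather stacks are NetCDF with time/lat/lon
dimensions and ``tmin``/``tmax`` variables (written with the NetCDF3
backend so no compiled HDF5 dependency is needed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import xarray as xr

from .landscape import ExtractionSummary, PresenceSet
from .traits import PreferenceSeries, SprintTrial, ToleranceRecord, TraitSummary

SPRINT_COLUMNS = ["individual", "season", "test_temp_C", "lap", "segment_index",
                  "time_s", "valid"]


def read_sprint_csv(path) -> list[SprintTrial]:
    """Read long-format sprint trials (one row per 0.25 m segment).

    Rows sharing (individual, season, test_temp_C) form one trial;
    segments are ordered by (lap, segment_index) with both laps
    concatenated. A trial is invalid if any of its rows is flagged
    invalid.
    """
    df = pd.read_csv(path)
    df["season"] = df["season"].fillna("")  # blank seasons must not drop rows
    trials = []
    for (ind, season, temp), grp in df.groupby(
        ["individual", "season", "test_temp_C"], sort=True
    ):
        grp = grp.sort_values(["lap", "segment_index"])
        trials.append(
            SprintTrial(
                individual_id=str(ind),
                test_temperature=float(temp),
                segment_times=tuple(grp["time_s"].astype(float)),
                valid=bool(grp["valid"].astype(bool).all()),
                season=str(season),
            )
        )
    return trials


def write_sprint_csv(trials: list[SprintTrial], path) -> None:
    rows = []
    for t in trials:
        n = len(t.segment_times)
        per_lap = max(n // 2, 1)
        for k, s in enumerate(t.segment_times):
            rows.append(
                {
                    "individual": t.individual_id,
                    "season": t.season,
                    "test_temp_C": t.test_temperature,
                    "lap": k // per_lap + 1,
                    "segment_index": k % per_lap + 1,
                    "time_s": s,
                    "valid": t.valid,
                }
            )
    pd.DataFrame(rows, columns=SPRINT_COLUMNS).to_csv(path, index=False)


def read_tolerance_csv(path) -> list[ToleranceRecord]:
    df = pd.read_csv(path)
    return [
        ToleranceRecord(
            individual_id=str(r["individual"]), season=str(r["season"]),
            ctmin=float(r["ctmin_C"]), ctgape=float(r["ctgape_C"]),
        )
        for _, r in df.iterrows()
    ]


def write_tolerance_csv(records: list[ToleranceRecord], path) -> None:
    pd.DataFrame(
        [
            {"individual": r.individual_id, "season": r.season,
             "ctmin_C": r.ctmin, "ctgape_C": r.ctgape, "tbreadth_C": r.tbreadth}
            for r in records
        ]
    ).to_csv(path, index=False)


def read_preference_csv(path) -> list[PreferenceSeries]:
    """Long format: individual, season, time_s, body_temp_C rows."""
    df = pd.read_csv(path)
    season = "season" in df.columns
    if season:
        df["season"] = df["season"].fillna("")
    out = []
    for key, grp in df.groupby(["individual"] + (["season"] if season else [])):
        ind = key[0] if isinstance(key, tuple) else key
        grp = grp.sort_values("time_s")
        out.append(
            PreferenceSeries(
                individual_id=str(ind),
                timestamps=tuple(grp["time_s"].astype(float)),
                body_temps=tuple(grp["body_temp_C"].astype(float)),
                season=str(key[1]) if season and isinstance(key, tuple) else "",
            )
        )
    return out


def write_preference_csv(series: list[PreferenceSeries], path) -> None:
    rows = []
    for s in series:
        for t, x in zip(s.timestamps, s.body_temps):
            rows.append(
                {"individual": s.individual_id, "season": s.season,
                 "time_s": t, "body_temp_C": x}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_trait_summary_csv(summary: TraitSummary, path) -> None:
    d = dataclasses.asdict(summary)
    lo, hi = d.pop("pref_range")
    d["pref_range_low"], d["pref_range_high"] = lo, hi
    pd.DataFrame([d]).to_csv(path, index=False)


def read_trait_summary_csv(path) -> TraitSummary:
    d = pd.read_csv(path).iloc[0].to_dict()
    return TraitSummary(
        mean_ctmin=d["mean_ctmin"], lowest_ctmin=d["lowest_ctmin"],
        mean_ctgape=d["mean_ctgape"], mean_tbreadth=d["mean_tbreadth"],
        tpref_mean=d["tpref_mean"], tpref_mode=d["tpref_mode"],
        tpref_sd=d["tpref_sd"],
        pref_range=(d["pref_range_low"], d["pref_range_high"]),
    )


def read_weather_stack(path) -> xr.Dataset:
    """Daily Tmin/Tmax NetCDF stack with time/lat/lon dimensions."""
    ds = xr.open_dataset(path, engine="scipy")
    ds.load()
    ds.close()
    return ds


def write_weather_stack(stack: xr.Dataset, path) -> None:
    stack = stack.copy()
    stack["time"] = stack["time"].astype("datetime64[s]")
    stack.to_netcdf(path, engine="scipy")


def write_metric_stack(metrics: xr.Dataset, path) -> None:
    """Metric rasters as one NetCDF file (variables on lat/lon)."""
    metrics.to_netcdf(path, engine="scipy")


def read_metric_stack(path) -> xr.Dataset:
    ds = xr.open_dataset(path, engine="scipy")
    ds.load()
    ds.close()
    return ds


def read_presences_csv(path) -> PresenceSet:
    """Presence localities CSV with ``lon,lat[,name]`` columns."""
    return PresenceSet.from_dataframe(pd.read_csv(path))


def write_presences_csv(presences: PresenceSet, path) -> None:
    pd.DataFrame(presences.points, columns=["lon", "lat"]).to_csv(path, index=False)


def write_extraction_csv(summary: ExtractionSummary, path) -> None:
    summary.to_frame().to_csv(path)


def write_ground_truth_json(obj, path) -> None:
    """Generator parameters as JSON next to simulated data files."""

    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    Path(path).write_text(json.dumps(obj, default=default, indent=1))
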