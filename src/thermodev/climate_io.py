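"""Ingesting daily gridded temperatures and building warming scenarios.

The primary interchange format is long-format delimited text with columns
``cell_id, lat, lon, year, doy, tmin, tmax`` (``year`` optional for
single-year climatologies, ``lat``/``lon`` optional throughout). Multi-year
records are averaged per cell and day-of-year into a daily climatology
before use; leap days (day-of-year 366) are dropped.

Future scenarios follow the delta-change method: the difference between a
projected and a current mean annual temperature — per cell, averaged over
climate-model projections when several are supplied — is added uniformly to
the daily minimum and maximum series. In-memory gridded data (xarray
Datasets with ``tmin``/``tmax`` variables) are supported behind the same
contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phenology import DAYS_PER_YEAR, DailyClimateSeries

__all__ = [
    "WarmingScenario",
    "read_daily_series",
    "write_daily_series",
    "build_climatology",
    "compute_delta",
    "apply_delta",
    "read_scenarios",
    "write_scenarios",
    "from_xarray",
    "to_xarray",
]


@dataclass(frozen=True)
class WarmingScenario:
    """Per-cell uniform warming offsets (°C) under one labelled scenario."""

    label: str
    delta_t: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = [c for c, d in self.delta_t.items() if not np.isfinite(d)]
        if bad:
            raise ValueError(f"non-finite delta for cell(s) {bad[:5]}")


# ---------------------------------------------------------------------------
# Delimited-text interchange


def _series_from_cell_frame(cell_id: str, df: pd.DataFrame) -> DailyClimateSeries:
    df = df.sort_values("doy")
    lat = float(df["lat"].iloc[0]) if "lat" in df and df["lat"].notna().all() else None
    lon = float(df["lon"].iloc[0]) if "lon" in df and df["lon"].notna().all() else None
    return DailyClimateSeries(
        cell_id=str(cell_id),
        tmin=df["tmin"].to_numpy(float),
        tmax=df["tmax"].to_numpy(float),
        latitude=lat, longitude=lon)


def read_daily_series(path) -> list[DailyClimateSeries]:
    """Read per-cell daily series from long-format delimited text.

    Files holding multiple years per cell are averaged into a climatology.
    """
    df = pd.read_csv(path)
    return build_climatology(df) if "year" in df.columns else [
        _series_from_cell_frame(cid, g) for cid, g in df.groupby("cell_id")]


def write_daily_series(series: Iterable[DailyClimateSeries], path) -> None:
    frames = []
    for s in series:
        frames.append(pd.DataFrame({
            "cell_id": s.cell_id, "lat": s.latitude, "lon": s.longitude,
            "doy": s.day_of_year, "tmin": s.tmin, "tmax": s.tmax}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Climatology


def build_climatology(records: pd.DataFrame) -> list[DailyClimateSeries]:
    """Per-cell, per-day-of-year mean of tmin/tmax across years.

    ``records`` is a long-format frame with columns ``cell_id, doy, tmin,
    tmax`` and optionally ``year``, ``lat``, ``lon``. Day-of-year 366 (leap
    day) is dropped. A missing (cell, year, doy) combination is a hard error
    listing the gaps, so silently unbalanced averages cannot occur.
    """
    df = records[records["doy"] <= DAYS_PER_YEAR].copy()
    if "year" in df.columns:
        gaps = []
        for (cid, year), g in df.groupby(["cell_id", "year"]):
            missing = set(range(1, DAYS_PER_YEAR + 1)) - set(g["doy"])
            if missing:
                gaps.append((cid, year, sorted(missing)[:5], len(missing)))
        if gaps:
            raise ValueError(f"incomplete cell-years (first 5): {gaps[:5]}")
    agg = (df.groupby(["cell_id", "doy"], sort=True)
             .agg({c: "mean" for c in df.columns
                   if c in ("lat", "lon", "tmin", "tmax")})
             .reset_index())
    return [_series_from_cell_frame(cid, g) for cid, g in agg.groupby("cell_id")]


# ---------------------------------------------------------------------------
# Delta-change scenarios


def compute_delta(
    current_annual_mean: Mapping[str, float],
    future_annual_mean: Mapping[str, float] | Sequence[Mapping[str, float]],
    label: str = "future",
) -> WarmingScenario:
    """Per-cell delta: (consensus) future mean annual T − current mean annual T.

    ``future_annual_mean`` may be a single projection or a sequence of
    projections (e.g. several general circulation models); in the latter case
    the deltas derive from the mean of the projections.
    """
    if isinstance(future_annual_mean, Mapping):
        projections = [future_annual_mean]
    else:
        projections = list(future_annual_mean)
    cells = set(current_annual_mean)
    for p in projections:
        if set(p) != cells:
            raise ValueError("projection cell set differs from the current one")
    deltas = {
        c: float(np.mean([p[c] for p in projections]) - current_annual_mean[c])
        for c in sorted(cells)}
    return WarmingScenario(label=label, delta_t=deltas)


def apply_delta(series: DailyClimateSeries,
                scenario: WarmingScenario) -> DailyClimateSeries:
    """Shift a cell's tmin and tmax by its scenario delta (preserves
    tmin ≤ tmax)."""
    if series.cell_id not in scenario.delta_t:
        raise KeyError(
            f"scenario {scenario.label!r} has no delta for cell "
            f"{series.cell_id!r}")
    return series.shifted(scenario.delta_t[series.cell_id])


def read_scenarios(path) -> dict[str, WarmingScenario]:
    df = pd.read_csv(path)
    return {
        str(label): WarmingScenario(
            label=str(label),
            delta_t={str(c): float(d)
                     for c, d in zip(g["cell_id"], g["delta_t"])})
        for label, g in df.groupby("label")}


def write_scenarios(scenarios: Iterable[WarmingScenario], path) -> None:
    rows = [{"cell_id": c, "label": s.label, "delta_t": d}
            for s in scenarios for c, d in s.delta_t.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gridded (xarray) ingestion, behind the same contract


def from_xarray(ds) -> list[DailyClimateSeries]:
    """Convert an xarray Dataset with ``tmin``/``tmax`` over (time|doy, cell)
    into per-cell series; multi-year time axes are averaged per day-of-year."""
    df = ds[["tmin", "tmax"]].to_dataframe().reset_index()
    if "doy" not in df.columns:
        if "time" not in df.columns:
            raise ValueError("dataset needs a 'doy' or 'time' coordinate")
        time = pd.to_datetime(df["time"])
        # drop leap days so every year maps onto the 365-day template
        df = df[~((time.dt.month == 2) & (time.dt.day == 29))].copy()
        time = pd.to_datetime(df["time"])
        df["year"] = time.dt.year
        df["doy"] = time.dt.dayofyear
        df.loc[time.dt.is_leap_year & (df["doy"] > 60), "doy"] -= 1
    if "cell" in df.columns:
        df = df.rename(columns={"cell": "cell_id"})
    return build_climatology(df)


def to_xarray(series: Sequence[DailyClimateSeries]):
    import xarray as xr

    cells = [s.cell_id for s in series]
    return xr.Dataset(
        {
            "tmin": (("cell", "doy"), np.stack([s.tmin for s in series])),
            "tmax": (("cell", "doy"), np.stack([s.tmax for s in series])),
        },
        coords={"cell": cells, "doy": np.arange(1, DAYS_PER_YEAR + 1)},
    )
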