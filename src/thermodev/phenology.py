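"""Voltinism and threshold-exceedance phenology from daily temperatures.

The daily development rate is the mean of the rates evaluated at the day's
minimum and maximum air temperature. Rates accumulate over consecutive days
from 1 January with an empty accumulator; each time the running total reaches
1 a generation is complete and the overshoot carries into the next one, so
the annual generation count is the number of completions plus the final
residual fraction — algebraically identical to the plain sum of daily rates.

Exceedance counts use the convention that a day is cold-limited when its
minimum is strictly below T_L and heat-limited when its maximum reaches or
exceeds T_H.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .models import ModelParams, ThermalThresholds, evaluate_rate

__all__ = [
    "DAYS_PER_YEAR",
    "DailyClimateSeries",
    "VoltinismResult",
    "ExceedanceResult",
    "daily_rate",
    "accumulate_development",
    "annual_generations",
    "percent_difference",
    "count_exceedance",
    "voltinism_map",
]

#: Climatological year length; leap days are dropped on ingestion.
DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class DailyClimateSeries:
    """One cell-year of daily minimum/maximum air temperature (°C).

    Exactly 365 days ordered by day-of-year, with tmin ≤ tmax every day.
    """

    cell_id: str
    tmin: np.ndarray
    tmax: np.ndarray
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        tmin = np.asarray(self.tmin, float)
        tmax = np.asarray(self.tmax, float)
        object.__setattr__(self, "tmin", tmin)
        object.__setattr__(self, "tmax", tmax)
        if tmin.shape != (DAYS_PER_YEAR,) or tmax.shape != (DAYS_PER_YEAR,):
            raise ValueError(
                f"cell {self.cell_id}: need exactly {DAYS_PER_YEAR} days, "
                f"got tmin {tmin.shape}, tmax {tmax.shape}")
        if not (np.all(np.isfinite(tmin)) and np.all(np.isfinite(tmax))):
            raise ValueError(f"cell {self.cell_id}: non-finite temperatures")
        bad = np.nonzero(tmin > tmax)[0]
        if bad.size:
            raise ValueError(
                f"cell {self.cell_id}: tmin > tmax on day(s) {bad[:5] + 1}")

    @property
    def day_of_year(self) -> np.ndarray:
        return np.arange(1, DAYS_PER_YEAR + 1)

    @property
    def tmean(self) -> np.ndarray:
        return 0.5 * (self.tmin + self.tmax)

    def annual_mean(self) -> float:
        """Annual mean temperature: mean of the daily (tmin+tmax)/2."""
        return float(self.tmean.mean())

    def shifted(self, delta_t: float) -> "DailyClimateSeries":
        """Series with both tmin and tmax shifted by ``delta_t`` °C."""
        return DailyClimateSeries(self.cell_id, self.tmin + delta_t,
                                  self.tmax + delta_t,
                                  self.latitude, self.longitude)


@dataclass(frozen=True)
class VoltinismResult:
    """Annual generation count for one cell under one scenario."""

    cell_id: str
    generations: float
    completion_days: tuple[int, ...]
    scenario: str = "current"

    @property
    def residual_fraction(self) -> float:
        return self.generations - len(self.completion_days)


@dataclass(frozen=True)
class ExceedanceResult:
    """Annual counts of threshold-exceeding days for one cell/scenario."""

    cell_id: str
    days_below_tl: int | None
    days_above_th: int | None
    scenario: str = "current"


def daily_rate(params: ModelParams, tmin, tmax):
    """Mean of the development rates at the daily minimum and maximum."""
    tmin = np.asarray(tmin, float)
    tmax = np.asarray(tmax, float)
    if np.any(tmin > tmax):
        raise ValueError("tmin exceeds tmax")
    return 0.5 * (evaluate_rate(params, tmin) + evaluate_rate(params, tmax))


def accumulate_development(rates: Sequence[float]) -> tuple[float, list[int]]:
    """Reset-with-carry accumulation of daily rates.

    Returns (total generations, 1-based days on which cumulative development
    reached 1). The carried overshoot makes the total equal to the plain sum
    of the rates.
    """
    rates = np.asarray(rates, float)
    if np.any(rates < 0):
        raise ValueError("negative development rate")
    cum = np.cumsum(rates)
    total = float(cum[-1])
    # tolerance so that e.g. ten days at rate 0.1 complete on day 10 despite
    # binary rounding of the running sum
    targets = np.arange(1.0, total + 1e-9)
    completions = np.searchsorted(cum, targets - 1e-9, side="left") + 1
    return total, [int(d) for d in completions]


def annual_generations(series: DailyClimateSeries, params: ModelParams,
                       scenario: str = "current") -> VoltinismResult:
    """Generations completed in one climatological year in one cell."""
    rates = daily_rate(params, series.tmin, series.tmax)
    total, days = accumulate_development(rates)
    return VoltinismResult(cell_id=series.cell_id, generations=total,
                           completion_days=tuple(days), scenario=scenario)


def percent_difference(current: float, future: float) -> float:
    """Relative change in generations, (future − current)/current × 100."""
    if current <= 0:
        raise ValueError("percent difference undefined for current <= 0")
    return (future - current) / current * 100.0


def count_exceedance(series: DailyClimateSeries,
                     thresholds: ThermalThresholds,
                     scenario: str = "current") -> ExceedanceResult:
    """Days with tmin strictly below T_L and days with tmax at or above T_H.

    A threshold the model does not estimate yields ``None`` for its count;
    at least one of T_L/T_H must be defined.
    """
    if thresholds.t_l is None and thresholds.t_h is None:
        raise ValueError("neither thermal threshold is defined")
    below = (int(np.sum(series.tmin < thresholds.t_l))
             if thresholds.t_l is not None else None)
    above = (int(np.sum(series.tmax >= thresholds.t_h))
             if thresholds.t_h is not None else None)
    return ExceedanceResult(cell_id=series.cell_id, days_below_tl=below,
                            days_above_th=above, scenario=scenario)


def voltinism_map(grid: Iterable[DailyClimateSeries], params: ModelParams,
                  scenario: str = "current") -> list[VoltinismResult]:
    """Apply :func:`annual_generations` to every cell of a grid.

    Failing cells are re-raised with the cell id attached rather than
    silently dropped.
    """
    results = []
    for series in grid:
        try:
            results.append(annual_generations(series, params, scenario))
        except Exception as exc:
            raise RuntimeError(
                f"voltinism failed for cell {series.cell_id!r}: {exc}"
            ) from exc
    return results


def summarize_generations(results: Sequence[VoltinismResult]) -> dict[str, float]:
    gens = [r.generations for r in results]
    return {"min": min(gens), "max": max(gens),
            "mean": float(np.mean(gens)), "n_cells": len(gens)}
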