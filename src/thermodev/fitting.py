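"""Fitting development-rate models and selecting the best one.

The fitting substrate is a set of (temperature, mean development time)
observations for one species and life stage; models are fitted to the
observed development *rate* (1/time, d⁻¹) by ordinary least squares (linear
model) or seeded multi-start bounded least squares with a trust-region
Levenberg–Marquardt-type solver (nonlinear models).

Model quality combines fit statistics with the biological plausibility of
the thermal thresholds each model implies:

* ``S``   = sqrt(SSE / (n − k)), the regression standard error,
* ``AIC`` = n·ln(SSE/n) + 2(k+1),
* ``BIC`` = n·ln(SSE/n) + (k+1)·ln(n),

with ΔAIC/ΔBIC taken against the per-comparison minimum (the error variance
is counted as one estimated parameter, hence k+1). Thresholds are screened
against species-specific plausibility windows; the best model maximizes the
number of plausible thresholds, breaking ties by ΔAIC and then by parsimony.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .models import (
    _RATE_FUNCS,
    MODEL_SPECS,
    ModelParams,
    ModelSpec,
    ParameterError,
    ThermalThresholds,
    derive_thresholds,
    evaluate_rate,
    make_params,
)

__all__ = [
    "DevelopmentDataset",
    "FitStatistics",
    "FittedModel",
    "PlausibilityRanges",
    "ModelComparison",
    "InsufficientDataError",
    "FitFailureError",
    "fit_linear",
    "fit_nonlinear",
    "fit_all",
    "compare_models",
    "screen_plausibility",
    "select_best",
    "DEFAULT_RANGES",
]


class InsufficientDataError(ValueError):
    """Raised when a dataset is too small for the requested fit."""


class FitFailureError(RuntimeError):
    """Raised when no multi-start attempt converges; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


# ---------------------------------------------------------------------------
# Data container


@dataclass(frozen=True)
class DevelopmentDataset:
    """Mean development time per constant temperature for one species/stage.

    ``temperatures`` must be strictly increasing with at least two distinct
    values; ``dev_times`` are mean egg-to-adult durations in days (> 0).
    ``se`` and ``n`` are optional per-temperature standard errors and
    replicate counts. ``censored_temperatures`` records temperatures at which
    no development completed (excluded from the rates).
    """

    species: str
    stage: str
    temperatures: tuple[float, ...]
    dev_times: tuple[float, ...]
    se: tuple[float, ...] | None = None
    n: tuple[int, ...] | None = None
    censored_temperatures: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, float)
        d = np.asarray(self.dev_times, float)
        if t.size != d.size:
            raise ValueError("temperatures and dev_times differ in length")
        if t.size < 2:
            raise InsufficientDataError("need at least 2 temperatures")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(d <= 0):
            raise ValueError("development times must be > 0")

    @property
    def rates(self) -> np.ndarray:
        """Observed development rates, 1/time (d⁻¹)."""
        return 1.0 / np.asarray(self.dev_times, float)

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.temperatures, float)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "species": self.species,
            "stage": self.stage,
            "temperature_c": self.temperatures,
            "dev_time_days": self.dev_times,
        })
        df["se_days"] = self.se if self.se is not None else np.nan
        df["n"] = self.n if self.n is not None else pd.NA
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DevelopmentDataset":
        df = df.sort_values("temperature_c")
        species = str(df["species"].iloc[0]) if "species" in df else "unknown"
        stage = str(df["stage"].iloc[0]) if "stage" in df else "unknown"
        se = tuple(df["se_days"]) if "se_days" in df and df["se_days"].notna().all() else None
        n = tuple(int(x) for x in df["n"]) if "n" in df and df["n"].notna().all() else None
        return cls(species, stage, tuple(df["temperature_c"]),
                   tuple(df["dev_time_days"]), se=se, n=n)

    @classmethod
    def from_csv(cls, path) -> "DevelopmentDataset":
        df = pd.read_csv(path)
        if df.empty:
            raise InsufficientDataError(f"no observations in {path}")
        return cls.from_frame(df)


# ---------------------------------------------------------------------------
# Fit statistics


@dataclass(frozen=True)
class FitStatistics:
    """Least-squares fit statistics under the SSE-based AIC/BIC convention."""

    sse: float
    n: int
    k: int
    s: float | None
    aic: float
    bic: float
    delta_aic: float | None = None
    delta_bic: float | None = None

    @classmethod
    def from_sse(cls, sse: float, n: int, k: int) -> "FitStatistics":
        s = math.sqrt(sse / (n - k)) if n > k else None
        if sse > 0:
            base = n * math.log(sse / n)
        else:  # perfect fit: criteria diverge to -inf, deltas still work
            base = float("-inf")
        aic = base + 2 * (k + 1)
        bic = base + (k + 1) * math.log(n)
        return cls(sse=float(sse), n=n, k=k, s=s, aic=aic, bic=bic)


@dataclass
class FittedModel:
    """A parameterized model with its provenance and fit statistics."""

    params: ModelParams
    dataset: DevelopmentDataset
    stats: FitStatistics | None
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return self.params.spec.name

    def thresholds(self) -> ThermalThresholds:
        return derive_thresholds(self.params)

    def predict(self, t):
        return evaluate_rate(self.params, t)


# ---------------------------------------------------------------------------
# Linear fit


def fit_linear(data: DevelopmentDataset) -> FittedModel:
    """Ordinary least squares of rate on temperature over all provided points.

    The lower threshold follows by the x-intercept method (T_L = −a/b) and
    the thermal constant as the reciprocal slope (K = 1/b); both are exposed
    through :meth:`FittedModel.thresholds`. With exactly two points the fit
    interpolates and S is reported undefined (n = k).
    """
    t, r = data.t, data.rates
    if t.size < 2:
        raise InsufficientDataError("linear fit needs at least 2 points")
    design = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(design, r, rcond=None)
    a, b = (float(c) for c in coef)
    sse = float(np.sum((r - design @ coef) ** 2))
    params = make_params("linear", {"a": a, "b": b})
    stats = FitStatistics.from_sse(sse, n=t.size, k=2)
    return FittedModel(params=params, dataset=data, stats=stats,
                       diagnostics={"method": "ols-normal-equations"})


# ---------------------------------------------------------------------------
# Nonlinear multi-start fit

# Wide per-parameter boxes. Thermal windows follow the species' biology
# (thresholds of temperate egg parasitoids); scale/shape boxes are generous
# because several forms (Brière-2 m, Logan-6 φ) sit on flat SSE ridges.
_DEFAULT_BOUNDS: dict[str, dict[str, tuple[float, float]]] = {
    "beta16": {"c_m": (1e-4, 10.0), "t_l": (-20.0, 20.0),
               "t_h": (30.0, 50.0), "t_opt": (20.0, 40.0)},
    "beta_type": {"rho": (1e-6, 1.0), "a": (1.0, 10.0), "beta": (0.1, 20.0)},
    "briere1": {"a": (1e-9, 1e-2), "t_l": (-20.0, 20.0), "t_h": (30.0, 50.0)},
    "briere2": {"a": (1e-9, 1e-2), "m": (1.0, 50.0),
                "t_l": (-20.0, 20.0), "t_h": (30.0, 50.0)},
    "kontodimas": {"alpha": (1e-9, 1e-2), "t_l": (-20.0, 20.0),
                   "t_h": (30.0, 50.0)},
    "lactin1": {"rho": (1e-4, 1.0), "delta": (0.1, 30.0), "t_h": (30.0, 50.0)},
    "lactin2": {"rho": (1e-4, 1.0), "delta": (0.1, 30.0),
                "lam": (-2.0, 1.0), "t_h": (30.0, 50.0)},
    "logan6": {"phi": (1e-6, 10.0), "rho": (1e-4, 1.0),
               "delta": (0.1, 30.0), "t_h": (30.0, 50.0)},
    "performance2": {"c": (1e-6, 1.0), "k": (1e-3, 20.0),
                     "t_l": (-20.0, 20.0), "t_h": (30.0, 50.0)},
    "shi": {"c": (1e-4, 100.0), "k1": (1e-6, 10.0), "k2": (1e-3, 20.0),
            "t_l": (-20.0, 20.0), "t_h": (30.0, 50.0)},
    "taylor": {"r_m": (1e-4, 1.0), "t_opt": (20.0, 40.0),
               "t_sigma": (1.0, 20.0)},
}


def default_bounds(name: str) -> dict[str, tuple[float, float]]:
    return {k: v for k, v in _DEFAULT_BOUNDS[name].items()}


def _anchor_start(data: DevelopmentDataset, spec: ModelSpec,
                  lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """One data-informed start: thresholds near the observed range, scale near
    the peak rate, shapes mid-box."""
    t, r = data.t, data.rates
    peak = float(np.max(r))
    guess = {
        "t_l": float(t.min()) - 3.0,
        "t_h": float(t.max()) + 3.0,
        "t_opt": float(t[np.argmax(r)]),
        "c_m": peak, "r_m": peak, "t_sigma": 8.0,
        "a": 1e-4, "m": 2.0, "alpha": 1e-5, "rho": 0.15, "delta": 6.0,
        "lam": -0.01, "phi": 0.01, "c": 0.01, "k": 1.0, "k1": 0.1, "k2": 3.0,
        "beta": 3.0, "b": 0.005,
    }
    if spec.name == "beta_type":
        guess["a"] = (float(t.max()) + 3.0) / 10.0  # upper zero at 10·a
        guess["rho"] = 0.01
    x0 = np.array([guess[p] for p in spec.parameter_names])
    return np.clip(x0, lo, hi)


def fit_nonlinear(
    data: DevelopmentDataset,
    model: str | ModelSpec,
    n_starts: int = 200,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> FittedModel:
    """Multi-start bounded least squares of one nonlinear model.

    Starts are a seeded Latin-hypercube sample of ``n_starts`` points within
    the per-parameter boxes, plus one data-informed anchor; each start is
    refined with scipy's trust-region-reflective solver and the converged fit
    with minimal SSE wins (ties by first found). The clamped rate function is
    fitted, so starts whose thermal window excludes the data simply score the
    flat zero curve and lose.
    """
    spec = MODEL_SPECS[model] if isinstance(model, str) else model
    if spec.name == "linear":
        return fit_linear(data)
    box = dict(_DEFAULT_BOUNDS[spec.name])
    if bounds:
        box.update(bounds)
    lo = np.array([box[p][0] for p in spec.parameter_names])
    hi = np.array([box[p][1] for p in spec.parameter_names])
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("bounds must be finite")
    t, r = data.t, data.rates
    names = spec.parameter_names

    def residuals(x: np.ndarray) -> np.ndarray:
        return _clamped(spec.name, dict(zip(names, x)), t) - r

    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)
    starts = np.vstack([_anchor_start(data, spec, lo, hi), starts])

    candidates = []
    start_sses = []
    n_failed = 0
    for i, x0 in enumerate(starts):
        start_sses.append(float(np.sum(residuals(x0) ** 2)))
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        except Exception:
            n_failed += 1
            continue
        if np.all(np.isfinite(res.x)):
            candidates.append((2.0 * float(res.cost), i, res.x))
    if not candidates:
        raise FitFailureError(
            f"no start converged for {spec.name}",
            diagnostics={"n_starts": len(starts), "n_failed": n_failed})
    candidates.sort(key=lambda c: (c[0], c[1]))
    best = None
    for sse, i, x in candidates:
        try:
            params = make_params(spec.name, dict(zip(names, x)))
        except ParameterError:
            continue  # disordered thermal window; next-best candidate
        best = (sse, i, params)
        break
    if best is None:
        raise FitFailureError(
            f"no converged {spec.name} fit satisfied the parameter "
            "invariants", diagnostics={"n_candidates": len(candidates)})
    sse, i, params = best
    stats = (FitStatistics.from_sse(sse, n=t.size, k=spec.k)
             if t.size >= spec.k else None)
    return FittedModel(
        params=params, dataset=data, stats=stats, converged=True,
        diagnostics={
            "n_starts": len(starts), "start_used": int(i),
            "n_converged": len(candidates), "n_failed": n_failed,
            "start_sse": start_sses, "seed": seed,
        })


def _clamped(name: str, values: Mapping[str, float], t: np.ndarray) -> np.ndarray:
    # evaluate without ModelParams validation (fit iterates may be disordered)
    raw = np.atleast_1d(_RATE_FUNCS[name](t, values))
    out = np.where(np.isfinite(raw), raw, 0.0)
    out = np.clip(out, 0.0, None)
    spec = MODEL_SPECS[name]
    if {"t_l", "t_h"} <= spec.explicit_thresholds:
        out[(t < values["t_l"]) | (t > values["t_h"])] = 0.0
    return out


def fit_all(data: DevelopmentDataset, models: Sequence[str] | None = None,
            n_starts: int = 200, seed: int = 0) -> list[FittedModel]:
    """Fit every requested model (default: all twelve) to ``data``.

    Each model gets an independent deterministic start sample derived from
    ``seed``.
    """
    models = list(models) if models is not None else list(MODEL_SPECS)
    fits = []
    for j, name in enumerate(models):
        if name == "linear":
            fits.append(fit_linear(data))
        else:
            fits.append(fit_nonlinear(data, name, n_starts=n_starts,
                                      seed=seed + 1009 * j))
    return fits


# ---------------------------------------------------------------------------
# Plausibility screening and model comparison

PLAUSIBLE, IMPLAUSIBLE, NOT_ESTIMATED = "+", "-", "•"


@dataclass(frozen=True)
class PlausibilityRanges:
    """Species-specific acceptance windows (°C) for T_L, T_opt and T_H."""

    ranges: Mapping[str, Mapping[str, tuple[float, float]]]

    def for_species(self, species: str) -> Mapping[str, tuple[float, float]]:
        try:
            return self.ranges[species]
        except KeyError:
            raise KeyError(
                f"no plausibility ranges defined for species {species!r}"
            ) from None


DEFAULT_RANGES = PlausibilityRanges({
    "telenomus_remus": {
        "t_l": (6.0, 15.0), "t_opt": (32.0, 34.0), "t_h": (34.0, 36.0)},
    "trichogramma_foersteri": {
        "t_l": (8.0, 15.0), "t_opt": (30.0, 32.0), "t_h": (32.0, 33.0)},
})


def screen_plausibility(
    thresholds: ThermalThresholds,
    ranges: PlausibilityRanges,
    species: str,
) -> dict[str, str]:
    """Mark each threshold '+' (defined, inside its closed range), '−'
    (defined, outside) or '•' (not estimated by the model)."""
    windows = ranges.for_species(species)
    marks = {}
    for key in ("t_l", "t_opt", "t_h"):
        value = getattr(thresholds, key)
        if value is None:
            marks[key] = NOT_ESTIMATED
        else:
            lo, hi = windows[key]
            marks[key] = PLAUSIBLE if lo <= value <= hi else IMPLAUSIBLE
    return marks


@dataclass(frozen=True)
class ComparisonEntry:
    fit: FittedModel
    stats: FitStatistics | None
    thresholds: ThermalThresholds
    marks: dict[str, str]

    @property
    def n_plus(self) -> int:
        return sum(1 for m in self.marks.values() if m == PLAUSIBLE)

    @property
    def n_defined(self) -> int:
        return len(self.thresholds.defined())


@dataclass(frozen=True)
class ModelComparison:
    """Per-model statistics, thresholds and plausibility marks for one dataset."""

    species: str
    entries: Mapping[str, ComparisonEntry]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, e in self.entries.items():
            st = e.stats
            rows.append({
                "model": name,
                "k": e.fit.params.spec.k,
                "sse": st.sse if st else np.nan,
                "s": st.s if st and st.s is not None else np.nan,
                "aic": st.aic if st else np.nan,
                "bic": st.bic if st else np.nan,
                "delta_aic": st.delta_aic if st else np.nan,
                "delta_bic": st.delta_bic if st else np.nan,
                "t_l": e.thresholds.t_l,
                "t_opt": e.thresholds.t_opt,
                "t_h": e.thresholds.t_h,
                "thermal_constant": e.thresholds.k,
                "mark_t_l": e.marks["t_l"],
                "mark_t_opt": e.marks["t_opt"],
                "mark_t_h": e.marks["t_h"],
                "n_plausible": e.n_plus,
                "n_estimated": e.n_defined,
            })
        return pd.DataFrame(rows)


def compare_models(
    fits: Iterable[FittedModel],
    ranges: PlausibilityRanges = DEFAULT_RANGES,
) -> ModelComparison:
    """Attach Δ-criteria (vs the per-set minima) and plausibility marks.

    All fits must share one dataset; ΔAIC/ΔBIC are computed over the fits
    that carry statistics, so exactly one model scores ΔAIC = 0.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("compare_models requires at least one fit")
    datasets = {id(f.dataset) for f in fits}
    if len(datasets) > 1:
        raise ValueError("all fits must share the same dataset")
    species = fits[0].dataset.species
    with_stats = [f for f in fits if f.stats is not None]
    min_aic = min((f.stats.aic for f in with_stats), default=math.nan)
    min_bic = min((f.stats.bic for f in with_stats), default=math.nan)
    entries: dict[str, ComparisonEntry] = {}
    for f in fits:
        stats = f.stats
        if stats is not None:
            # identity comparison keeps Δ = 0 exact even for perfect fits
            # whose criteria diverge to -inf
            d_aic = 0.0 if stats.aic == min_aic else stats.aic - min_aic
            d_bic = 0.0 if stats.bic == min_bic else stats.bic - min_bic
            stats = replace(stats, delta_aic=d_aic, delta_bic=d_bic)
        thr = f.thresholds()
        marks = screen_plausibility(thr, ranges, species)
        entries[f.name] = ComparisonEntry(fit=f, stats=stats,
                                          thresholds=thr, marks=marks)
    return ModelComparison(species=species, entries=entries)


def select_best(comparison: ModelComparison) -> str:
    """Lexicographic selection: most plausible thresholds, then lowest ΔAIC,
    then fewest parameters (alphabetical order as the deterministic last
    resort)."""
    if not comparison.entries:
        raise ValueError("empty comparison")

    def sort_key(item):
        name, e = item
        delta = (e.stats.delta_aic
                 if e.stats is not None and e.stats.delta_aic is not None
                 else math.inf)
        return (-e.n_plus, delta, e.fit.params.spec.k, name)

    return min(comparison.entries.items(), key=sort_key)[0]
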