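"""Temperature-dependent development-rate models for insects.

This module defines the twelve rate functions commonly fitted to constant-
temperature development data of ectotherms (one linear, eleven nonlinear),
evaluates them safely over arbitrary temperatures, and derives the
biologically meaningful thermal parameters:

* ``T_L``  — lower thermal threshold, below which development stops (°C),
* ``T_opt`` — temperature of maximal development rate (°C),
* ``T_H``  — upper thermal threshold, above which development stops (°C),
* ``K``   — thermal constant of the linear model (degree-days).

Rates are development per day (d⁻¹, the reciprocal of development time in
days); temperatures are °C throughout. Where a raw formula is negative,
complex-valued, or outside the model's thermal window, the evaluated rate is
clamped to exactly zero so that downstream phenology accumulation is total
over any daily temperature input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "MODEL_NAMES",
    "MODEL_SPECS",
    "ModelSpec",
    "ModelParams",
    "ThermalThresholds",
    "ParameterError",
    "UnknownModelError",
    "DegenerateOptimumError",
    "evaluate_rate",
    "derive_topt",
    "derive_thresholds",
]


class UnknownModelError(KeyError):
    """Raised when a model name is not one of the twelve known forms."""


class ParameterError(ValueError):
    """Raised when a parameter vector does not match its model spec."""


class DegenerateOptimumError(RuntimeError):
    """Raised when a model has no interior rate maximum (e.g. the linear model)."""


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of one development-rate function.

    ``explicit_thresholds`` names the thermal parameters that appear as free
    parameters of the functional form itself; the remaining thresholds are
    derived numerically (or undefined for that model). ``zero_at`` is the
    subset of explicit thresholds at which the raw formula itself vanishes —
    used by invariant tests and by the evaluation clamp.
    """

    name: str
    parameter_names: tuple[str, ...]
    explicit_thresholds: frozenset[str] = frozenset()
    zero_at: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(set(self.parameter_names)) != len(self.parameter_names):
            raise ParameterError(f"duplicate parameter names in {self.name}")
        if not self.explicit_thresholds <= {"t_l", "t_opt", "t_h"}:
            raise ParameterError(f"invalid explicit thresholds for {self.name}")

    @property
    def k(self) -> int:
        """Number of free parameters of the form."""
        return len(self.parameter_names)


def _spec(name, params, explicit=(), zero=()):
    return ModelSpec(name, tuple(params), frozenset(explicit), frozenset(zero))


#: The twelve supported model forms, keyed by name.
MODEL_SPECS: dict[str, ModelSpec] = {
    s.name: s
    for s in (
        _spec("linear", ("a", "b")),
        _spec("beta16", ("c_m", "t_l", "t_h", "t_opt"),
              explicit=("t_l", "t_h", "t_opt"), zero=("t_l", "t_h")),
        _spec("beta_type", ("rho", "a", "beta")),
        _spec("briere1", ("a", "t_l", "t_h"),
              explicit=("t_l", "t_h"), zero=("t_l", "t_h")),
        _spec("briere2", ("a", "m", "t_l", "t_h"),
              explicit=("t_l", "t_h"), zero=("t_l", "t_h")),
        _spec("kontodimas", ("alpha", "t_l", "t_h"),
              explicit=("t_l", "t_h"), zero=("t_l", "t_h")),
        _spec("lactin1", ("rho", "delta", "t_h"),
              explicit=("t_h",), zero=("t_h",)),
        _spec("lactin2", ("rho", "delta", "lam", "t_h"),
              explicit=("t_h",)),
        _spec("logan6", ("phi", "rho", "delta", "t_h"),
              explicit=("t_h",), zero=("t_h",)),
        _spec("performance2", ("c", "k", "t_l", "t_h"),
              explicit=("t_l", "t_h"), zero=("t_l", "t_h")),
        _spec("shi", ("c", "k1", "k2", "t_l", "t_h"),
              explicit=("t_l", "t_h"), zero=("t_l", "t_h")),
        _spec("taylor", ("r_m", "t_opt", "t_sigma"),
              explicit=("t_opt",)),
    )
}

MODEL_NAMES: tuple[str, ...] = tuple(MODEL_SPECS)

#: Rate-scale parameters that must be strictly positive.
_POSITIVE = {"c_m", "a", "alpha", "phi", "c", "r_m"}
# 'a' is positive for every model that uses it as a rate scale; the linear
# intercept is also named 'a' but may be negative, so exempt it there.


@dataclass(frozen=True)
class ModelParams:
    """A model spec bound to concrete parameter values."""

    spec: ModelSpec
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(self.spec.parameter_names) - set(self.values)
        if missing:
            raise ParameterError(
                f"{self.spec.name}: missing parameter(s) {sorted(missing)}")
        extra = set(self.values) - set(self.spec.parameter_names)
        if extra:
            raise ParameterError(
                f"{self.spec.name}: unknown parameter(s) {sorted(extra)}")
        for k, v in self.values.items():
            if not np.isfinite(v):
                raise ParameterError(f"{self.spec.name}: {k} is not finite")
        v = self.values
        pieces = [v.get("t_l"), v.get("t_opt"), v.get("t_h")]
        present = [p for p in pieces if p is not None]
        if len(present) > 1 and any(np.diff(present) <= 0):
            raise ParameterError(
                f"{self.spec.name}: thermal parameters must be ordered "
                f"t_l < t_opt < t_h, got {present}")
        if self.spec.name != "linear":
            for k in self.spec.parameter_names:
                if k in _POSITIVE and v[k] <= 0:
                    raise ParameterError(f"{self.spec.name}: {k} must be > 0")

    def __getitem__(self, key: str) -> float:
        return float(self.values[key])


def make_params(name: str, values: Mapping[str, float]) -> ModelParams:
    """Build :class:`ModelParams` for model ``name``, validating the vector."""
    try:
        spec = MODEL_SPECS[name]
    except KeyError:
        raise UnknownModelError(
            f"unknown model {name!r}; expected one of {sorted(MODEL_SPECS)}"
        ) from None
    return ModelParams(spec, dict(values))


# ---------------------------------------------------------------------------
# Raw formulas. Each takes a float array t and a parameter mapping and returns
# the unclamped model value; NaN marks complex/undefined regions.

def _f_linear(t, v):
    return v["a"] + v["b"] * t


def _f_beta16(t, v):
    # Canonical beta rate function: peak c_m at t_opt, zeros at t_l and t_h.
    tl, th, topt = v["t_l"], v["t_h"], v["t_opt"]
    expo = (topt - tl) / (th - topt)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        base = (t - tl) / (topt - tl)
        return v["c_m"] * ((th - t) / (th - topt)) * np.float_power(base, expo)


def _f_beta_type(t, v):
    with np.errstate(invalid="ignore", over="ignore"):
        return v["rho"] * (v["a"] - t / 10.0) * np.float_power(t / 10.0, v["beta"])


def _briere(t, a, m, tl, th):
    with np.errstate(invalid="ignore", over="ignore"):
        return a * t * (t - tl) * np.float_power(th - t, 1.0 / m)


def _f_briere1(t, v):
    return _briere(t, v["a"], 2.0, v["t_l"], v["t_h"])


def _f_briere2(t, v):
    return _briere(t, v["a"], v["m"], v["t_l"], v["t_h"])


def _f_kontodimas(t, v):
    return v["alpha"] * (t - v["t_l"]) ** 2 * (v["t_h"] - t)


def _lactin_core(t, rho, delta, th):
    with np.errstate(over="ignore"):
        return np.exp(rho * t) - np.exp(rho * th - (th - t) / delta)


def _f_lactin1(t, v):
    return _lactin_core(t, v["rho"], v["delta"], v["t_h"])


def _f_lactin2(t, v):
    return _lactin_core(t, v["rho"], v["delta"], v["t_h"]) + v["lam"]


def _f_logan6(t, v):
    return v["phi"] * _lactin_core(t, v["rho"], v["delta"], v["t_h"])


def _f_performance2(t, v):
    with np.errstate(over="ignore"):
        return v["c"] * (t - v["t_l"]) * (1.0 - np.exp(v["k"] * (t - v["t_h"])))


def _f_shi(t, v):
    with np.errstate(over="ignore"):
        return (v["c"]
                * (1.0 - np.exp(-v["k1"] * (t - v["t_l"])))
                * (1.0 - np.exp(v["k2"] * (t - v["t_h"]))))


def _f_taylor(t, v):
    return v["r_m"] * np.exp(-0.5 * ((t - v["t_opt"]) / v["t_sigma"]) ** 2)


_RATE_FUNCS: dict[str, Callable] = {
    "linear": _f_linear,
    "beta16": _f_beta16,
    "beta_type": _f_beta_type,
    "briere1": _f_briere1,
    "briere2": _f_briere2,
    "kontodimas": _f_kontodimas,
    "lactin1": _f_lactin1,
    "lactin2": _f_lactin2,
    "logan6": _f_logan6,
    "performance2": _f_performance2,
    "shi": _f_shi,
    "taylor": _f_taylor,
}


def raw_rate(params: ModelParams, t) -> np.ndarray:
    """Unclamped model value (may be negative or NaN); mainly for root finding."""
    return _RATE_FUNCS[params.spec.name](np.asarray(t, dtype=float), params.values)


def evaluate_rate(params: ModelParams, t):
    """Development rate (d⁻¹, ≥ 0) of ``params`` at temperature(s) ``t`` (°C).

    The raw formula is clamped to exactly 0 wherever it is negative,
    complex-valued, or outside the model's explicit thermal window
    ``[t_l, t_h]``. Scalar input returns a scalar; sequences vectorize
    elementwise.
    """
    arr = np.asarray(t, dtype=float)
    scalar = arr.ndim == 0
    arr1 = np.atleast_1d(arr)
    raw = np.atleast_1d(_RATE_FUNCS[params.spec.name](arr1, params.values))
    out = np.where(np.isfinite(raw), raw, 0.0)
    out = np.clip(out, 0.0, None)
    v = params.values
    # models whose window is fully parametric (both thresholds explicit):
    # outside it the raw algebra can be spuriously positive (e.g. Brière below
    # t_l at t < 0, Kontodimas below t_l), so zero the window explicitly.
    if {"t_l", "t_h"} <= params.spec.explicit_thresholds:
        out[(arr1 < v["t_l"]) | (arr1 > v["t_h"])] = 0.0
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Threshold derivation


def _scan_domain(params: ModelParams) -> tuple[float, float]:
    """Temperature interval scanned for the rate maximum."""
    name, v = params.spec.name, params.values
    if {"t_l", "t_h"} <= params.spec.explicit_thresholds:
        return v["t_l"], v["t_h"]
    if name in ("lactin1", "lactin2", "logan6"):
        return v["t_h"] - 80.0, v["t_h"]
    if name == "beta_type":
        return 0.0, 10.0 * v["a"]
    raise DegenerateOptimumError(
        f"{name} has no interior rate maximum to search for")


def derive_topt(params: ModelParams, step: float = 0.01) -> float:
    """Optimum temperature: argmax of :func:`evaluate_rate`.

    Explicit-parameter models (beta16, taylor) pass the parameter through;
    otherwise a dense grid scan (default step 0.01 °C) followed by bounded
    local refinement locates the maximum. A flat or boundary-only maximum
    raises :class:`DegenerateOptimumError`.
    """
    if "t_opt" in params.spec.explicit_thresholds:
        return params["t_opt"]
    lo, hi = _scan_domain(params)
    grid = np.arange(lo, hi + step / 2.0, step)
    vals = evaluate_rate(params, grid)
    i = int(np.argmax(vals))
    if vals[i] <= 0.0:
        raise DegenerateOptimumError(
            f"{params.spec.name}: rate non-positive over the scan domain")
    if i == 0 or i == len(grid) - 1:
        raise DegenerateOptimumError(
            f"{params.spec.name}: rate maximum on the domain boundary")
    res = minimize_scalar(
        lambda x: -evaluate_rate(params, float(x)),
        bounds=(grid[i - 1], grid[i + 1]),
        method="bounded",
        options={"xatol": 1e-7},
    )
    return float(res.x)


@dataclass(frozen=True)
class ThermalThresholds:
    """Thermal thresholds of a parameterized model.

    ``None`` marks a threshold the model does not define. ``provenance`` maps
    each defined field to ``explicit-parameter`` or ``derived-numerically``
    and each undefined one to ``undefined-by-model``. ``k`` (degree-days) is
    defined for the linear model only, as the reciprocal slope.
    """

    t_l: float | None = None
    t_opt: float | None = None
    t_h: float | None = None
    k: float | None = None
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        present = [x for x in (self.t_l, self.t_opt, self.t_h) if x is not None]
        if len(present) > 1 and any(np.diff(present) <= 0):
            raise ParameterError(
                f"thresholds must be ordered t_l < t_opt < t_h, got {present}")

    def defined(self) -> dict[str, float]:
        return {k: v for k, v in
                (("t_l", self.t_l), ("t_opt", self.t_opt), ("t_h", self.t_h))
                if v is not None}


_UNDEFINED = "undefined-by-model"
_EXPLICIT = "explicit-parameter"
_DERIVED = "derived-numerically"


def _zero_crossing(params: ModelParams, start: float, direction: int,
                   max_span: float = 120.0, coarse: float = 0.5) -> float | None:
    """Nearest strict sign change of the raw formula from ``start`` towards
    ``direction`` (−1 below / +1 above), refined with brentq; None if the raw
    value never becomes negative within ``max_span`` degrees."""
    f = lambda x: float(raw_rate(params, x))
    prev = start
    fprev = f(prev)
    if not np.isfinite(fprev) or fprev <= 0:
        return None
    steps = int(max_span / coarse)
    for j in range(1, steps + 1):
        x = start + direction * j * coarse
        fx = f(x)
        if not np.isfinite(fx):
            return None  # formula leaves the real domain before reaching zero
        if fx <= 0.0:
            a, b = (x, prev) if direction < 0 else (prev, x)
            if fx == 0.0:
                return x
            return float(brentq(f, a, b, xtol=1e-10))
        prev, fprev = x, fx
    return None


def derive_thresholds(params: ModelParams) -> ThermalThresholds:
    """All thermal thresholds of ``params``, explicit or numerically derived.

    For each of ``t_l``/``t_h`` the explicit parameter is used when the form
    has one; otherwise the zero of the rate curve nearest below/above the
    optimum is located by bracketed root search; when no finite zero exists on
    that side (linear above, lactin-1/logan-6/β-type below, taylor both) the
    threshold is reported undefined rather than raising.
    """
    name, v = params.spec.name, params.values
    prov: dict[str, str] = {}

    if name == "linear":
        if v["b"] > 0:
            tl, k = -v["a"] / v["b"], 1.0 / v["b"]
            prov = {"t_l": _DERIVED, "t_opt": _UNDEFINED,
                    "t_h": _UNDEFINED, "k": _DERIVED}
            return ThermalThresholds(t_l=tl, k=k, provenance=prov)
        prov = dict.fromkeys(("t_l", "t_opt", "t_h", "k"), _UNDEFINED)
        return ThermalThresholds(provenance=prov)

    explicit = params.spec.explicit_thresholds
    try:
        topt = derive_topt(params)
        prov["t_opt"] = _EXPLICIT if "t_opt" in explicit else _DERIVED
    except DegenerateOptimumError:
        topt = None
        prov["t_opt"] = _UNDEFINED

    out: dict[str, float | None] = {"t_l": None, "t_h": None}
    for key, direction in (("t_l", -1), ("t_h", +1)):
        if key in explicit:
            out[key] = v[key]
            prov[key] = _EXPLICIT
        elif topt is not None:
            root = _zero_crossing(params, topt, direction)
            out[key] = root
            prov[key] = _DERIVED if root is not None else _UNDEFINED
        else:
            prov[key] = _UNDEFINED
    prov["k"] = _UNDEFINED
    return ThermalThresholds(t_l=out["t_l"], t_opt=topt, t_h=out["t_h"],
                             provenance=prov)
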