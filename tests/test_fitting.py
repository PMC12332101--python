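"""Least-squares fitting, fit statistics, screening and model selection."""

import math
from dataclasses import replace

import numpy as np
import pytest

import thermodev as td
from thermodev.fitting import (
    DEFAULT_RANGES,
    ComparisonEntry,
    FitStatistics,
    ModelComparison,
)


def dataset_from_rates(temps, rates, species="telenomus_remus"):
    return td.DevelopmentDataset(
        species=species, stage="egg_adult",
        temperatures=tuple(temps), dev_times=tuple(1.0 / np.asarray(rates)))


# ---------------------------------------------------------------------------
# linear fit


def test_linear_fit_recovers_exact_line():
    temps = [15.0, 20.0, 25.0]
    data = dataset_from_rates(temps, [0.01 * (t - 10.0) for t in temps])
    fit = td.fit_linear(data)
    assert fit.params["a"] == pytest.approx(-0.1, abs=1e-12)
    assert fit.params["b"] == pytest.approx(0.01, abs=1e-14)
    thr = fit.thresholds()
    assert thr.t_l == pytest.approx(10.0, abs=1e-9)
    assert thr.k == pytest.approx(100.0, abs=1e-9)
    assert fit.stats.sse == pytest.approx(0.0, abs=1e-20)


def test_linear_fit_two_points_flags_s_undefined():
    data = dataset_from_rates([20.0, 30.0], [0.05, 0.12])
    fit = td.fit_linear(data)
    assert fit.stats.s is None          # n = k: no residual degrees of freedom
    assert fit.predict(20.0) == pytest.approx(0.05, abs=1e-12)
    assert fit.predict(30.0) == pytest.approx(0.12, abs=1e-12)


def test_linear_fit_matches_statsmodels_ols(remus_data):
    sm = pytest.importorskip("statsmodels.api")
    fit = td.fit_linear(remus_data)
    ols = sm.OLS(remus_data.rates, sm.add_constant(remus_data.t)).fit()
    assert fit.params["a"] == pytest.approx(ols.params[0], abs=1e-12)
    assert fit.params["b"] == pytest.approx(ols.params[1], abs=1e-12)
    assert fit.stats.sse == pytest.approx(ols.ssr, rel=1e-12)


def test_linear_fit_reproduces_published_block(remus_data):
    fit = td.fit_linear(remus_data)
    assert fit.params["b"] == pytest.approx(5.65e-3, rel=0.01)
    assert fit.params["a"] == pytest.approx(-0.06, abs=0.01)
    thr = fit.thresholds()
    assert thr.t_l == pytest.approx(11.16, abs=0.05)
    assert thr.k == pytest.approx(176.94, abs=0.5)


def test_insufficient_data_raises():
    with pytest.raises((td.InsufficientDataError, ValueError)):
        td.DevelopmentDataset(species="x", stage="y",
                              temperatures=(20.0,), dev_times=(10.0,))


# ---------------------------------------------------------------------------
# nonlinear multi-start fit


def test_nonlinear_noise_free_recovery_kontodimas():
    true = td.make_params("kontodimas",
                          {"alpha": 1.63e-5, "t_l": 9.5, "t_h": 46.79})
    temps = np.linspace(14.0, 35.0, 8)
    data = dataset_from_rates(temps, td.evaluate_rate(true, temps))
    fit = td.fit_nonlinear(data, "kontodimas", n_starts=40, seed=3)
    for key, value in true.values.items():
        assert fit.params[key] == pytest.approx(value, rel=1e-4), key


def test_nonlinear_descent_property(remus_data):
    """The returned SSE never exceeds the SSE at any multi-start point."""
    for name in ("briere1", "taylor", "performance2"):
        fit = td.fit_nonlinear(remus_data, name, n_starts=30, seed=11)
        assert fit.stats.sse <= min(fit.diagnostics["start_sse"]) + 1e-15


def test_nonlinear_fit_is_seeded_deterministic(remus_data):
    a = td.fit_nonlinear(remus_data, "briere1", n_starts=25, seed=5)
    b = td.fit_nonlinear(remus_data, "briere1", n_starts=25, seed=5)
    assert a.params.values == b.params.values


def test_statistics_suppressed_when_underdetermined():
    data = dataset_from_rates([20.0, 25.0, 30.0, 33.0], [0.05, 0.08, 0.12, 0.125])
    fit = td.fit_nonlinear(data, "shi", n_starts=15, seed=1)  # k=5 > n=4
    assert fit.stats is None
    assert set(fit.params.values) == {"c", "k1", "k2", "t_l", "t_h"}


def test_parameter_recovery_with_rate_noise():
    """Simulated rate data (σ = 1e-3) recover T_L/T_H within 1.5 °C in ≥ 80%
    of seeded replicates, for the four well-identified threshold models."""
    temps = np.linspace(14.0, 35.0, 8)
    truths = {
        "briere1": {"a": 6.51e-5, "t_l": 11.73, "t_h": 40.53},
        "kontodimas": {"alpha": 1.63e-5, "t_l": 9.5, "t_h": 46.79},
        "performance2": {"c": 6.78e-3, "k": 3.43, "t_l": 12.63, "t_h": 35.49},
        "shi": {"c": 0.20, "k1": 4.97e-2, "k2": 8.57, "t_l": 11.87, "t_h": 32.22},
    }
    n_rep = 25
    for name, values in truths.items():
        true = td.make_params(name, values)
        clean = td.evaluate_rate(true, temps)
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(n_rep):
            noisy = np.clip(clean + 1e-3 * rng.standard_normal(temps.size),
                            1e-4, None)
            data = dataset_from_rates(temps, noisy)
            fit = td.fit_nonlinear(data, name, n_starts=24, seed=7)
            if (abs(fit.params["t_l"] - values["t_l"]) < 1.5
                    and abs(fit.params["t_h"] - values["t_h"]) < 1.5):
                hits += 1
        assert hits >= 0.8 * n_rep, name


# ---------------------------------------------------------------------------
# statistics, screening, selection


def test_fit_statistics_formulas():
    st = FitStatistics.from_sse(sse=3.59e-4, n=5, k=2)
    assert st.s == pytest.approx(math.sqrt(3.59e-4 / 3))
    assert st.aic == pytest.approx(5 * math.log(3.59e-4 / 5) + 6)
    assert st.bic == pytest.approx(5 * math.log(3.59e-4 / 5) + 3 * math.log(5))


def test_delta_criteria_invariant_to_additive_constant(remus_data):
    fits = [td.fit_linear(remus_data),
            td.fit_nonlinear(remus_data, "taylor", n_starts=30, seed=2)]
    base = td.compare_models(fits)
    shifted = [replace(f.stats, aic=f.stats.aic + 7.7, bic=f.stats.bic + 7.7)
               for f in fits]
    deltas = [e.stats.delta_aic for e in base.entries.values()]
    shifted_min = min(s.aic for s in shifted)
    assert [s.aic - shifted_min for s in shifted] == pytest.approx(deltas)


def test_compare_single_fit_has_zero_deltas(remus_data):
    cmp_ = td.compare_models([td.fit_linear(remus_data)])
    entry = cmp_.entries["linear"]
    assert entry.stats.delta_aic == 0.0
    assert entry.stats.delta_bic == 0.0
    assert td.select_best(cmp_) == "linear"


def test_compare_requires_shared_dataset(remus_data):
    other = dataset_from_rates([15.0, 25.0, 35.0], [0.02, 0.08, 0.12])
    with pytest.raises(ValueError):
        td.compare_models([td.fit_linear(remus_data), td.fit_linear(other)])
    with pytest.raises(ValueError):
        td.compare_models([])


@pytest.mark.parametrize(
    "thresholds, expected",
    [
        (dict(t_l=-17.89, t_opt=32.96, t_h=40.07), ("-", "+", "-")),
        (dict(t_l=11.16), ("+", "•", "•")),      # linear: only T_L estimated
        (dict(t_l=8.72, t_opt=34.00, t_h=35.04), ("+", "+", "+")),
    ],
)
def test_screen_plausibility_marks(thresholds, expected):
    thr = td.ThermalThresholds(**thresholds)
    marks = td.screen_plausibility(thr, DEFAULT_RANGES, "telenomus_remus")
    assert (marks["t_l"], marks["t_opt"], marks["t_h"]) == expected


def _entry(name, marks, delta_aic, k, remus_data, remus_params):
    stats = replace(FitStatistics.from_sse(1e-4, 5, k), delta_aic=delta_aic,
                    delta_bic=delta_aic)
    fit = td.FittedModel(params=remus_params[name], dataset=remus_data,
                         stats=stats)
    return ComparisonEntry(fit=fit, stats=stats, thresholds=fit.thresholds(),
                           marks=dict(zip(("t_l", "t_opt", "t_h"), marks)))


def test_select_best_prefers_threshold_count_over_fit(remus_data, remus_params):
    """A model with three plausible thresholds beats a better-fitting model
    with two, per the lexicographic rule."""
    comparison = ModelComparison(species="telenomus_remus", entries={
        "performance2": _entry("performance2", "+++", 3.0, 4,
                               remus_data, remus_params),
        "briere1": _entry("briere1", ("+", "+", "-"), 0.0, 3,
                          remus_data, remus_params),
    })
    assert td.select_best(comparison) == "performance2"


def test_select_best_invariant_to_input_order(remus_data):
    fits = td.fit_all(remus_data,
                      ["linear", "briere1", "taylor", "kontodimas"],
                      n_starts=40, seed=9)
    best_fwd = td.select_best(td.compare_models(fits))
    best_rev = td.select_best(td.compare_models(fits[::-1]))
    assert best_fwd == best_rev
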