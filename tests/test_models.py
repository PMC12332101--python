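"""Rate evaluation and thermal-threshold derivation."""

import numpy as np
import pytest

import thermodev as td
from thermodev.models import MODEL_SPECS, raw_rate


def briere2_remus():
    return td.make_params(
        "briere2", {"a": 1.69e-4, "m": 14.22, "t_l": 8.72, "t_h": 35.04})


@pytest.mark.parametrize(
    "t, expected",
    [
        # direct hand evaluation of a·T·(T−T_L)·(T_H−T)^(1/m); the observed
        # rate at 25 °C is 1/12.49 = 0.0801 d⁻¹
        (25.0, 0.0809),
        (8.72, 0.0),    # rate vanishes at the lower threshold
        (36.0, 0.0),    # clamped above the upper threshold
        (-5.0, 0.0),    # the raw cubic is positive below 0 °C; window clamps it
    ],
)
def test_briere2_point_evaluations(t, expected):
    assert td.evaluate_rate(briere2_remus(), t) == pytest.approx(expected, abs=5e-4)


def test_evaluate_rate_vectorizes_and_matches_scalar():
    p = briere2_remus()
    grid = np.array([-10.0, 8.72, 20.0, 34.0, 35.04, 50.0])
    vec = td.evaluate_rate(p, grid)
    assert vec.shape == grid.shape
    assert vec.tolist() == [td.evaluate_rate(p, float(t)) for t in grid]


def test_parameter_validation_errors():
    with pytest.raises(td.ParameterError):
        td.make_params("briere2", {"a": 1.69e-4, "m": 14.22, "t_l": 8.72})
    with pytest.raises(td.UnknownModelError):
        td.make_params("gaussian", {"a": 1.0})
    with pytest.raises(td.ParameterError):  # disordered thermal window
        td.make_params("briere1", {"a": 1e-4, "t_l": 40.0, "t_h": 10.0})


def _all_param_sets(all_reference_params):
    for species, sets in all_reference_params.items():
        for name, params in sets.items():
            yield species, name, params


def test_rate_nonnegative_everywhere(all_reference_params):
    grid = np.linspace(-40.0, 60.0, 2001)
    for species, name, params in _all_param_sets(all_reference_params):
        rates = td.evaluate_rate(params, grid)
        assert np.all(rates >= 0.0), (species, name)
        assert np.all(np.isfinite(rates)), (species, name)


def test_rate_vanishes_at_explicit_thresholds(all_reference_params):
    """Forms whose algebra pins a zero at an explicit threshold honour it."""
    checked = 0
    for species, name, params in _all_param_sets(all_reference_params):
        for key in MODEL_SPECS[name].zero_at:
            assert td.evaluate_rate(params, params[key]) <= 1e-12, (species, name, key)
            checked += 1
    assert checked > 10


def test_rate_positive_at_window_midpoint(all_reference_params):
    for species, name, params in _all_param_sets(all_reference_params):
        thr = td.derive_thresholds(params)
        if thr.t_l is not None and thr.t_h is not None:
            mid = 0.5 * (thr.t_l + thr.t_h)
            assert td.evaluate_rate(params, mid) > 0.0, (species, name)


def test_topt_agrees_with_dense_grid_oracle(all_reference_params):
    """derive_topt matches a brute-force 10⁻³ °C grid maximization."""
    for species, name, params in _all_param_sets(all_reference_params):
        if name == "linear":
            continue
        grid = np.arange(-20.0, 60.0, 1e-3)
        oracle = grid[np.argmax(td.evaluate_rate(params, grid))]
        topt = td.derive_topt(params)
        assert topt == pytest.approx(oracle, abs=0.01), (species, name)
        thr = td.derive_thresholds(params)
        if thr.t_l is not None and thr.t_h is not None:
            assert thr.t_l < topt < thr.t_h, (species, name)


@pytest.mark.parametrize(
    "species, name, printed_topt",
    [
        ("telenomus_remus", "briere2", 34.00),
        ("trichogramma_foersteri", "shi", 31.60),
        ("telenomus_remus", "taylor", 33.44),   # explicit-parameter passthrough
        ("telenomus_remus", "kontodimas", 34.40),
    ],
)
def test_topt_reproduces_published_values(all_reference_params, species, name,
                                          printed_topt):
    params = all_reference_params[species][name]
    assert td.derive_topt(params) == pytest.approx(printed_topt, abs=0.05)


def test_kontodimas_topt_closed_form(remus_params):
    # argmax of α(T−T_L)²(T_H−T) is (2·T_H + T_L)/3
    p = remus_params["kontodimas"]
    expected = (2 * p["t_h"] + p["t_l"]) / 3.0
    assert td.derive_topt(p) == pytest.approx(expected, abs=1e-4)


def test_linear_has_no_interior_optimum(remus_params):
    with pytest.raises(td.DegenerateOptimumError):
        td.derive_topt(remus_params["linear"])


def test_linear_threshold_algebra():
    p = td.make_params("linear", {"a": -0.0631, "b": 5.652e-3})
    thr = td.derive_thresholds(p)
    assert thr.t_l * p["b"] + p["a"] == pytest.approx(0.0, abs=1e-15)
    assert thr.k * p["b"] == pytest.approx(1.0, abs=1e-15)
    assert thr.t_opt is None and thr.t_h is None
    assert thr.provenance["t_h"] == "undefined-by-model"
    # published x-intercept: T_L = 11.16 °C, K = 176.94 degree-days
    assert thr.t_l == pytest.approx(11.16, abs=0.05)
    assert thr.k == pytest.approx(176.94, rel=0.005)


def test_linear_negative_slope_gives_undefined_thresholds():
    p = td.make_params("linear", {"a": 0.1, "b": -1e-3})
    thr = td.derive_thresholds(p)
    assert thr.t_l is None and thr.k is None


def test_taylor_thresholds_undefined(remus_params):
    """The Gaussian form has no finite zeros, so only T_opt is defined."""
    thr = td.derive_thresholds(remus_params["taylor"])
    assert thr.t_l is None and thr.t_h is None
    assert thr.t_opt == 33.44
    assert thr.provenance["t_l"] == "undefined-by-model"


def test_lactin1_lower_threshold_undefined(remus_params):
    thr = td.derive_thresholds(remus_params["lactin1"])
    assert thr.t_l is None
    assert thr.t_h == 38.53  # explicit parameter


def test_derived_roots_are_zeros_of_the_raw_curve(all_reference_params):
    """Numerically derived T_L/T_H sit on actual zero crossings."""
    checked = 0
    for species, name, params in _all_param_sets(all_reference_params):
        if name == "linear":
            continue
        thr = td.derive_thresholds(params)
        for key in ("t_l", "t_h"):
            if thr.provenance[key] == "derived-numerically":
                root = getattr(thr, key)
                assert abs(float(raw_rate(params, root))) < 1e-7, (species, name, key)
                checked += 1
    assert checked >= 4  # lactin2 T_L and beta_type T_H for both species


def test_beta_type_upper_threshold_closed_form(all_reference_params):
    # the β-type rate is ρ(a − T/10)(T/10)^β, so its upper zero is 10·a
    for species in all_reference_params:
        p = all_reference_params[species]["beta_type"]
        thr = td.derive_thresholds(p)
        assert thr.t_h == pytest.approx(10 * p["a"], abs=1e-6)
        assert thr.t_l is None


def test_threshold_ordering_invariant(all_reference_params):
    for species, name, params in _all_param_sets(all_reference_params):
        thr = td.derive_thresholds(params)
        defined = [v for v in (thr.t_l, thr.t_opt, thr.t_h) if v is not None]
        assert defined == sorted(defined), (species, name)
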