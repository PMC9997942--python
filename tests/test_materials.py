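import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitriflow.materials import (PropertyPolynomial, PropertyRangeError,
                                 ViscosityModel, calibrate_viscosity,
                                 evaluate_property, perturb_density_slope,
                                 viscosity)


@pytest.mark.parametrize("material,prop,T,expected", [
    ("cpa", "density", 0.0, 1090.0),
    ("cpa", "conductivity", 0.0, 0.356),
    ("cpa", "density", 10.0, 1083.1037),
    ("cuvette", "density", 0.0, 1055.0),
    ("cpa", "specific_heat", 0.0, 2804.0),
    ("cuvette", "conductivity", 0.0, 0.14),
])
def test_published_property_values(mats, material, prop, T, expected):
    poly = getattr(getattr(mats, material), prop)
    assert evaluate_property(poly, T) == pytest.approx(expected, rel=1e-12)


@settings(derandomize=True, max_examples=50)
@given(coeffs=st.lists(st.floats(-10, 10), min_size=1, max_size=6),
       T=st.floats(-140, 30))
def test_polynomial_matches_direct_summation(coeffs, T):
    poly = PropertyPolynomial(tuple(coeffs), name="random")
    direct = sum(c * T**i for i, c in enumerate(coeffs))
    assert evaluate_property(poly, T) == pytest.approx(direct, rel=1e-12, abs=1e-12)


def test_out_of_range_clamps_with_warning_or_raises(mats, caplog):
    poly = mats.cpa.density
    with caplog.at_level("WARNING"):
        v = evaluate_property(poly, -200.0)
    assert v == pytest.approx(evaluate_property(poly, poly.valid_range[0]))
    assert any("clamp" in r.message for r in caplog.records)
    strict = PropertyPolynomial(poly.coefficients, name="strict", clamp=False)
    with pytest.raises(PropertyRangeError, match="strict"):
        evaluate_property(strict, -200.0)


def test_density_strictly_increases_on_cooling(mats):
    T = np.linspace(-135.0, 10.0, 500)
    rho = evaluate_property(mats.cpa.density, T)
    assert np.all(np.diff(rho) < 0)  # decreasing with increasing T


def test_viscosity_anchor_points_and_log_midpoint():
    m = ViscosityModel()
    assert viscosity(m, m.T_ref, cap=False) == pytest.approx(m.mu_ref)
    assert viscosity(m, m.T_glass, cap=False) == pytest.approx(m.mu_glass, rel=1e-9)
    mid = 0.5 * (m.T_ref + m.T_glass)
    assert viscosity(m, mid, cap=False) == pytest.approx(
        math.sqrt(m.mu_ref * m.mu_glass), rel=1e-9)


def test_viscosity_cap_and_monotonicity():
    m = ViscosityModel(mu_cap=1e8)
    T = np.linspace(10.0, -135.0, 300)
    mu = viscosity(m, T)
    assert np.all(np.diff(mu) >= 0)          # grows as T decreases
    assert mu.max() == pytest.approx(1e8)
    assert viscosity(m, -132.0) == pytest.approx(1e8)


def test_viscosity_spans_fourteen_decades():
    m = ViscosityModel()
    ratio = viscosity(m, m.T_glass, cap=False) / viscosity(m, m.T_ref, cap=False)
    assert ratio >= 1e14 * (1 - 1e-9)


def test_calibrate_viscosity_closed_form_and_invariance():
    m = calibrate_viscosity(1e-2, 10.0, 1e12, -132.0)
    assert m.b == pytest.approx(math.log(1e14) / 142.0, rel=1e-12)
    assert m.b == pytest.approx(0.2270, abs=2e-4)
    doubled = calibrate_viscosity(2e-2, 10.0, 2e12, -132.0)
    assert doubled.b == pytest.approx(m.b, rel=1e-12)  # ratio-only dependence


@pytest.mark.parametrize("kwargs", [
    dict(mu_ref=1e-2, T_ref=10.0, mu_glass=1e-2, T_glass=-132.0),  # b = 0
    dict(mu_ref=1e-2, T_ref=-140.0, mu_glass=1e12, T_glass=10.0),  # inverted
    dict(mu_ref=-1e-2, T_ref=10.0, mu_glass=1e12, T_glass=-132.0),
])
def test_degenerate_viscosity_anchors_raise(kwargs):
    with pytest.raises(ValueError):
        calibrate_viscosity(**kwargs)


def test_perturb_density_slope(mats):
    rho = mats.cpa.density
    assert perturb_density_slope(rho, 1.0).coefficients == rho.coefficients
    steeper = perturb_density_slope(rho, 1.15)
    assert evaluate_property(steeper, 0.0) == pytest.approx(1090.0)
    diff = evaluate_property(steeper, -100.0) - evaluate_property(rho, -100.0)
    assert diff == pytest.approx(0.15 * (0.6922 * 100 + 0.000257 * 100**2),
                                 rel=1e-12)
    assert diff == pytest.approx(10.77, abs=0.01)
    with pytest.raises(ValueError):
        perturb_density_slope(rho, 0.0)


def test_default_material_set_constants(mats):
    assert mats.cpa.thermal_expansion == pytest.approx(1.1e-5)
    assert mats.cuvette.thermal_expansion == pytest.approx(8e-5)
    assert mats.h_free == 10.0 and mats.h_forced == 350.0
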