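import math

import numpy as np
import pytest

from vitriflow.fixtures import generate_synthetic_frames
from vitriflow.macroscopy import (FrameMeasurement, UncertaintyBudget,
                                  depth_uncertainty,
                                  displacement_uncertainty, reference_width,
                                  repeatability_percent, surface_displacement,
                                  validation_summary, width_uncertainty)

# the six cooling-rate / final-temperature study cases:
# (10, 15, 20, 25) C/min to -125 C and 20 C/min to (-115, -135) C
EXPERIMENT_MM = [4.26, 5.41, 6.12, 6.37, 3.92, 8.61]
MODEL_MM = [3.77, 4.87, 5.01, 5.67, 3.41, 10.04]


def test_reference_width():
    assert reference_width(10.18, 10.18) == pytest.approx(10.18)
    assert reference_width(10.0, 11.0) == pytest.approx(10.5)
    assert reference_width(9.7, 10.3) == reference_width(10.3, 9.7)
    with pytest.raises(ValueError):
        reference_width(0.0, 10.0)


def _frame(Hp, Lp=10.18, Le=10.0, t=0.0):
    return FrameMeasurement(Hp=Hp, Lp_front=Lp, Lp_back=Lp, Le=Le, time=t)


def test_surface_displacement_cases():
    frames = [_frame(2.0, t=t) for t in range(4)]
    assert surface_displacement(frames) == pytest.approx(np.zeros(4))
    moving = [_frame(2.0), _frame(3.018, t=1.0)]   # Hp grew by 1.018 screen mm
    us = surface_displacement(moving)
    assert us[1] == pytest.approx(1.018 * 10.0 / 10.18)
    doubled = [FrameMeasurement(f.Hp, f.Lp_front, f.Lp_back, 2 * f.Le, f.time)
               for f in moving]
    assert surface_displacement(doubled)[1] == pytest.approx(2 * us[1])
    with pytest.raises(ValueError):
        surface_displacement(moving[:1])


def test_synthetic_frames_invert_reduction_exactly():
    series = np.array([0.0, -0.8, -2.3, -5.01])
    frames = generate_synthetic_frames(series, scale_px_per_mm=1.7,
                                       noise_sd=0.0, seed=0, He0=6.0)
    assert surface_displacement(frames) == pytest.approx(series, abs=1e-12)
    again = generate_synthetic_frames(series, 1.7, 0.05, seed=123, He0=6.0)
    twice = generate_synthetic_frames(series, 1.7, 0.05, seed=123, He0=6.0)
    assert [f.Hp for f in again] == [f.Hp for f in twice]  # seed determinism


def test_depth_uncertainty():
    assert depth_uncertainty([2.0, 2.0, 2.0]) == 0.0
    assert depth_uncertainty([1.0, 3.0]) == pytest.approx(2 * math.sqrt(2))
    shifted = depth_uncertainty(np.array([1.0, 3.0]) + 5.0)
    assert shifted == pytest.approx(2 * math.sqrt(2))  # shift invariance
    assert depth_uncertainty([1.0, 4.0]) == pytest.approx(
        3 * depth_uncertainty([1.0, 2.0]))             # linear in spread
    with pytest.raises(ValueError):
        depth_uncertainty([1.0])


def test_depth_uncertainty_monte_carlo_matches_repetition_scheme():
    # 10 repeated readings with sd 0.055 mm give ~2*0.055 = 0.11 mm on
    # average over many seeds (the published repetition scheme)
    rng = np.random.default_rng(2024)
    vals = [depth_uncertainty(rng.normal(12.1, 0.055, 10)) for _ in range(400)]
    assert np.mean(vals) == pytest.approx(0.11, abs=0.01)


def test_width_uncertainty():
    assert width_uncertainty(0.11) == pytest.approx(0.19, abs=5e-3)
    assert round(width_uncertainty(0.11), 2) == 0.19
    assert width_uncertainty(0.0) == 0.0
    assert width_uncertainty(0.2) == pytest.approx(0.3464, abs=1e-4)
    with pytest.raises(ValueError):
        width_uncertainty(-0.1)


def test_displacement_uncertainty_reductions():
    frame = _frame(12.1)
    zero = UncertaintyBudget(dHp=0.0, dLp=0.0, dLe=0.0)
    assert displacement_uncertainty(frame, zero) == 0.0
    only_h = UncertaintyBudget(dHp=0.11, dLp=0.0, dLe=0.0)
    assert displacement_uncertainty(frame, only_h) == pytest.approx(
        frame.Le / frame.Lp * 0.11)


def test_displacement_uncertainty_finite_difference_oracle():
    rng = np.random.default_rng(17)
    budget = UncertaintyBudget(dHp=0.11, dLp=0.19, dLe=0.1)

    def he(hp, lp, le):
        return hp * le / lp

    for _ in range(25):
        hp = rng.uniform(2.0, 15.0)
        lp = rng.uniform(8.0, 12.0)
        le = rng.uniform(9.0, 11.0)
        frame = FrameMeasurement(Hp=hp, Lp_front=lp, Lp_back=lp, Le=le)
        eps = 1e-7
        dh = (he(hp + eps, lp, le) - he(hp - eps, lp, le)) / (2 * eps)
        dl = (he(hp, lp + eps, le) - he(hp, lp - eps, le)) / (2 * eps)
        de = (he(hp, lp, le + eps) - he(hp, lp, le - eps)) / (2 * eps)
        expect = math.sqrt((dh * budget.dHp) ** 2 + (dl * budget.dLp) ** 2
                           + (de * budget.dLe) ** 2)
        assert displacement_uncertainty(frame, budget) == pytest.approx(
            expect, abs=1e-6)


def test_displacement_uncertainty_screen_zoom_invariance():
    budget = UncertaintyBudget(dHp=0.11, dLp=0.19, dLe=0.1)
    base = _frame(12.1)
    du0 = displacement_uncertainty(base, budget)
    for s in (0.5, 2.0, 7.3):
        frame = FrameMeasurement(Hp=12.1 * s, Lp_front=10.18 * s,
                                 Lp_back=10.18 * s, Le=10.0)
        scaled = UncertaintyBudget(dHp=0.11 * s, dLp=0.19 * s, dLe=0.1)
        assert displacement_uncertainty(frame, scaled) == pytest.approx(du0)


def test_repeatability_percent():
    assert repeatability_percent(5.48, 0.15) == pytest.approx(2.74, abs=5e-3)
    assert repeatability_percent(7.0, 0.0) == 0.0
    assert repeatability_percent(10.0, 1.0) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        repeatability_percent(0.0, 0.1)


def test_validation_summary_published_pairs():
    out = validation_summary(EXPERIMENT_MM, MODEL_MM)
    assert out["mean_pct"] == pytest.approx(13.4, abs=0.1)
    assert out["max_pct"] == pytest.approx(18.1, abs=0.1)
    assert out["argmax_case"] == 2      # (20 C/min, -125 C)
    single = validation_summary([6.12], [5.01])
    assert single["max_pct"] == pytest.approx(18.1, abs=0.05)
    ident = validation_summary([1.0, 2.0], [1.0, 2.0])
    assert ident["mean_pct"] == 0.0 and ident["max_pct"] == 0.0
    with pytest.raises(ValueError):
        validation_summary([1.0, 2.0], [1.0])


def test_frame_validation():
    with pytest.raises(ValueError):
        FrameMeasurement(Hp=-1.0, Lp_front=10.0, Lp_back=10.0, Le=10.0)
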