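"""Cryomacroscopy data reduction and measurement uncertainty.

The cryomacroscope measures the free-surface cavity on the computer screen:
the on-screen cavity height H_p is converted to a physical height through
the known inner cuvette width, H_e = H_p * L_e / L_p, where the on-screen
reference width L_p is the mean of the apparent front and back inner widths
(the two faces appear at different scales because of depth of field).  The
centerline displacement is u_s(t) = H_e(t) - H_e(0).

Uncertainty model: the on-screen length uncertainty dH_p is twice the
sample standard deviation of repeated cavity-depth readings; the width
uncertainty is sqrt(3) dH_p (an average of two additional on-screen
measurements); the caliper uncertainty of the physical width is dL_e
(0.1 mm).  These propagate through H_e by first-order partial derivatives,
and displayed error bars equal +/- 2 du_s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FrameMeasurement", "UncertaintyBudget", "reference_width",
           "surface_displacement", "depth_uncertainty", "width_uncertainty",
           "displacement_uncertainty", "repeatability_percent",
           "validation_summary", "read_frames", "frames_to_dataframe",
           "metrics_report"]

FRAME_COLUMNS = ["time_s", "Hp_mm", "Lp_front_mm", "Lp_back_mm", "Le_mm"]


@dataclass(frozen=True)
class FrameMeasurement:
    """Pixel-converted on-screen measurements for one video frame (mm)."""

    Hp: float                 # on-screen cavity height from the reference line
    Lp_front: float           # apparent inner width, front face
    Lp_back: float            # apparent inner width, back face
    Le: float                 # physical inner width (caliper)
    time: float = 0.0         # s
    chamber_T: float = float("nan")  # degC, optional

    def __post_init__(self):
        if min(self.Hp, self.Lp_front, self.Lp_back, self.Le) <= 0:
            raise ValueError("all frame lengths must be positive")

    @property
    def Lp(self) -> float:
        return reference_width(self.Lp_front, self.Lp_back)

    @property
    def He(self) -> float:
        return self.Hp * self.Le / self.Lp


@dataclass(frozen=True)
class UncertaintyBudget:
    dHp: float = 0.11         # mm, on-screen height uncertainty (2 sd)
    dLp: float = 0.19         # mm, on-screen width uncertainty
    dLe: float = 0.1          # mm, caliper uncertainty
    dUs: float = float("nan")  # mm, propagated (filled by the pipeline)
    n_repeats: int = 10

    def __post_init__(self):
        for name in ("dHp", "dLp", "dLe"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def reference_width(Lp_front: float, Lp_back: float) -> float:
    """On-screen reference width: mean of front and back apparent widths."""
    if Lp_front <= 0 or Lp_back <= 0:
        raise ValueError("apparent widths must be positive")
    return 0.5 * (Lp_front + Lp_back)


def surface_displacement(frames) -> np.ndarray:
    """u_s(t) = H_e(t) - H_e(0) (mm) for an ordered frame sequence.

    The first frame is the reference; the returned series starts at 0.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least a reference frame and one measurement")
    he = np.array([f.He for f in frames])
    return he - he[0]


def depth_uncertainty(repeats) -> float:
    """Twice the sample standard deviation of repeated H_p readings (mm)."""
    repeats = np.asarray(repeats, dtype=float)
    if repeats.size < 2:
        raise ValueError("at least two repeated measurements required")
    return 2.0 * float(np.std(repeats, ddof=1))


def width_uncertainty(dHp: float) -> float:
    """dL_p = sqrt(3) dH_p (width from an average of two extra readings)."""
    if dHp < 0:
        raise ValueError("dHp must be non-negative")
    return math.sqrt(3.0) * dHp


def displacement_uncertainty(frame: FrameMeasurement,
                             budget: UncertaintyBudget) -> float:
    """First-order propagated uncertainty of u_s for one frame (mm).

    Partials are taken on H_e(t) = H_p L_e / L_p (the reference-frame term
    is not double-counted): dHe/dHp = Le/Lp, dHe/dLp = -Hp Le/Lp^2,
    dHe/dLe = Hp/Lp.
    """
    lp = frame.Lp
    if lp == 0:
        raise ValueError("zero reference width")
    for name in ("dHp", "dLp", "dLe"):
        if not math.isfinite(getattr(budget, name)):
            raise ValueError(f"budget component {name} must be finite")
    t1 = (frame.Le / lp) * budget.dHp
    t2 = (frame.Hp * frame.Le / lp**2) * budget.dLp
    t3 = (frame.Hp / lp) * budget.dLe
    return math.sqrt(t1 * t1 + t2 * t2 + t3 * t3)


def repeatability_percent(mean_depth: float, half_spread: float) -> float:
    """Experiment-to-experiment variability as percent of full depth."""
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    return half_spread / mean_depth * 100.0


def validation_summary(experimental_max, model_max) -> dict:
    """Per-case relative model-vs-experiment differences (percent).

    Returns mean and max of 100 |exp - mod| / exp and the index of the
    worst case.
    """
    exp = np.asarray(experimental_max, dtype=float)
    mod = np.asarray(model_max, dtype=float)
    if exp.shape != mod.shape or exp.ndim != 1 or exp.size == 0:
        raise ValueError("experimental and model lists must match and be non-empty")
    if np.any(exp <= 0) or np.any(mod <= 0):
        raise ValueError("displacement magnitudes must be positive")
    pct = 100.0 * np.abs(exp - mod) / exp
    idx = int(np.argmax(pct))
    return {"mean_pct": float(pct.mean()), "max_pct": float(pct.max()),
            "argmax_case": idx, "per_case_pct": pct}


# ---------------------------------------------------------------------------
# CSV front end
# ---------------------------------------------------------------------------

def read_frames(path) -> list:
    """Read per-frame measurements from CSV (columns: time_s, Hp_mm,
    Lp_front_mm, Lp_back_mm, Le_mm [, chamber_T_C])."""
    df = pd.read_csv(path)
    missing = [c for c in FRAME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"frames CSV missing column(s): {missing}")
    frames = []
    for _, row in df.iterrows():
        frames.append(FrameMeasurement(
            Hp=row["Hp_mm"], Lp_front=row["Lp_front_mm"],
            Lp_back=row["Lp_back_mm"], Le=row["Le_mm"], time=row["time_s"],
            chamber_T=row.get("chamber_T_C", float("nan"))))
    return frames


def frames_to_dataframe(frames) -> pd.DataFrame:
    return pd.DataFrame({
        "time_s": [f.time for f in frames],
        "Hp_mm": [f.Hp for f in frames],
        "Lp_front_mm": [f.Lp_front for f in frames],
        "Lp_back_mm": [f.Lp_back for f in frames],
        "Le_mm": [f.Le for f in frames],
    })


def metrics_report(frames, dLe: float = 0.1, dHp: float | None = None) -> pd.DataFrame:
    """Full reduction of a frame sequence: u_s, du_s and error bars.

    ``dHp`` defaults to the repeat-based estimate from the frame heights'
    scatter being unavailable per-frame: the budget value 0.11 mm.
    """
    frames = list(frames)
    us = surface_displacement(frames)
    budget = UncertaintyBudget(dHp=0.11 if dHp is None else dHp,
                               dLp=width_uncertainty(0.11 if dHp is None else dHp),
                               dLe=dLe)
    dus = np.array([displacement_uncertainty(f, budget) for f in frames])
    return pd.DataFrame({
        "time_s": [f.time for f in frames],
        "u_s_mm": us,
        "du_s_mm": dus,
        "errorbar_mm": 2.0 * dus,
    })
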