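"""Indirect calorimetry: Brockway energy expenditure and steady-state truth.

Breath-by-breath VO2/VCO2 (mL/min) is converted to metabolic power in watts
with the Brockway equation, EE_W = (16.58 VO2 + 4.51 VCO2) / 60, using the
standard per-millilitre energy equivalents of O2 and CO2 and omitting the
urinary-nitrogen term.  The per-trial ground truth is the mean EE over the
last four minutes of steady-state activity — the window ending where the
active period ends (the final minute of each trial is quiet standing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .simulator import BreathSeries, TrialCondition

__all__ = [
    "EESeries",
    "GroundTruthEE",
    "brockway_ee",
    "ee_series",
    "steady_state_window",
    "ground_truth_ee",
    "trial_ground_truth",
]

#: Brockway energy equivalents, joules per mL of O2 and CO2.
O2_J_PER_ML = 16.58
CO2_J_PER_ML = 4.51

#: Length of the steady-state averaging window, seconds.
STEADY_WINDOW_S = 240.0


@dataclass
class EESeries:
    """Energy expenditure sampled at breath times, watts."""

    times_s: np.ndarray
    ee_w: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.ee_w = np.asarray(self.ee_w, dtype=float)
        if len(self.times_s) != len(self.ee_w):
            raise ValueError("times and values must have equal length")
        if len(self.times_s) > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times_s must be strictly increasing")
        if not np.all(np.isfinite(self.ee_w)):
            raise ValueError("ee_w must be finite")


@dataclass(frozen=True)
class GroundTruthEE:
    """Steady-state EE scalar and the averaging window that produced it."""

    ee_w: float
    window_s: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.ee_w <= 0:
            raise ValueError("ee_w must be > 0")


def brockway_ee(vo2_ml_min: float, vco2_ml_min: float):
    """Metabolic power in watts from VO2 and VCO2 in mL/min.

    Linear in both inputs and zero at zero; accepts scalars or arrays.
    """
    vo2 = np.asarray(vo2_ml_min, dtype=float)
    vco2 = np.asarray(vco2_ml_min, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ValueError("gas-exchange rates must be >= 0")
    out = (O2_J_PER_ML * vo2 + CO2_J_PER_ML * vco2) / 60.0
    return float(out) if out.ndim == 0 else out


def ee_series(breaths: BreathSeries) -> EESeries:
    """Element-wise Brockway EE at each breath time."""
    if len(breaths.times_s) == 0:
        return EESeries(times_s=np.array([]), ee_w=np.array([]))
    return EESeries(
        times_s=breaths.times_s.copy(),
        ee_w=brockway_ee(breaths.vo2_ml_min, breaths.vco2_ml_min),
    )


def steady_state_window(condition: TrialCondition) -> Tuple[float, float]:
    """The last-four-minutes-of-activity averaging interval (start, end), s.

    The window is anchored to the end of the ACTIVE period: end = duration
    minus the standing margin, start = end - 240 s.  Raises if the active
    period is shorter than the window.
    """
    active_len = condition.duration_s - 2.0 * condition.standing_margin_s
    if active_len < STEADY_WINDOW_S:
        raise ValueError(
            f"active period {active_len:g} s shorter than the "
            f"{STEADY_WINDOW_S:g} s steady-state window"
        )
    end = condition.duration_s - condition.standing_margin_s
    return (end - STEADY_WINDOW_S, end)


def ground_truth_ee(series: EESeries, condition: TrialCondition) -> GroundTruthEE:
    """Mean EE over breaths falling in the half-open steady window [start, end)."""
    start, end = steady_state_window(condition)
    mask = (series.times_s >= start) & (series.times_s < end)
    if not np.any(mask):
        raise ValueError("no breaths inside the steady-state window")
    return GroundTruthEE(ee_w=float(np.mean(series.ee_w[mask])), window_s=(start, end))


def trial_ground_truth(breaths: BreathSeries, condition: TrialCondition) -> GroundTruthEE:
    """Convenience: Brockway conversion plus steady-state averaging in one call."""
    return ground_truth_ee(ee_series(breaths), condition)
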