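"""Melting-curve processing and transition (Tm) detection.

An RNA melting experiment with an ssRNA-sensitive fluorescent dye records
relative fluorescence units (RFU) while heating from ~37 to 95 degC. The
raw signal combines a temperature-driven dye-fluorescence decay with
inflections where structural elements unfold; plotting the negative
temperature derivative, -dRFU/dT, turns each unfolding transition into a
local maximum whose position is the melting temperature Tm.

Processing chain: per-replicate min-max normalization -> numerical
derivative (central differences, one-sided at the ends) -> replicate
averaging -> moving-average smoothing over a temperature window (default
1.5 degC, grid-independent) -> prominence-thresholded peak picking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

__all__ = [
    "MeltCurve",
    "DerivativeCurve",
    "Transition",
    "MeltTransitionDetector",
    "normalize_curve",
    "derivative",
    "average_and_smooth",
    "find_transitions",
    "compare_titration",
    "read_melt_csv",
]


@dataclass
class MeltCurve:
    """Fluorescence vs temperature for one replicate."""

    temperatures: np.ndarray  # degC, strictly increasing
    rfu: np.ndarray
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.temperatures.shape != self.rfu.shape:
            raise ValueError("temperature and rfu arrays must match")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperature grid must be strictly increasing")


@dataclass
class DerivativeCurve:
    """-dRFU/dT on the same temperature grid as its source curve."""

    temperatures: np.ndarray
    minus_drfu_dt: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.minus_drfu_dt = np.asarray(self.minus_drfu_dt, dtype=float)
        if self.temperatures.shape != self.minus_drfu_dt.shape:
            raise ValueError("grids must match")


class Transition(NamedTuple):
    tm_C: float
    height: float
    prominence: float


def normalize_curve(curve: MeltCurve) -> MeltCurve:
    """Min-max scale the fluorescence to [0, 1] (order-preserving)."""
    if len(curve.rfu) < 10:
        raise ValueError("melt curve needs at least 10 points")
    lo, hi = float(np.min(curve.rfu)), float(np.max(curve.rfu))
    if hi == lo:
        raise ValueError("constant fluorescence curve has no dynamic range")
    return MeltCurve(curve.temperatures.copy(), (curve.rfu - lo) / (hi - lo), curve.replicate_id)


def derivative(curve: MeltCurve) -> DerivativeCurve:
    """-dRFU/dT via central differences (one-sided at the grid ends)."""
    return DerivativeCurve(
        curve.temperatures.copy(), -np.gradient(curve.rfu, curve.temperatures)
    )


def average_and_smooth(
    derivs: Sequence[DerivativeCurve], window_C: float = 1.5
) -> DerivativeCurve:
    """Average replicate derivatives, then smooth over a temperature window.

    The smoother is a centered moving average covering ``window_C`` degrees
    (all grid points within +/- window_C/2), so its behaviour does not
    depend on the grid step; ``window_C = 0`` averages without smoothing.
    Near the ends the window simply truncates.
    """
    if not derivs:
        raise ValueError("no derivative curves given")
    grid = derivs[0].temperatures
    for d in derivs[1:]:
        if d.temperatures.shape != grid.shape or not np.allclose(d.temperatures, grid):
            raise ValueError("replicate derivative grids differ; resample first")
    mean = np.mean([d.minus_drfu_dt for d in derivs], axis=0)
    if window_C <= 0:
        return DerivativeCurve(grid.copy(), mean)
    half = window_C / 2.0
    smoothed = np.empty_like(mean)
    # O(n) sliding window over the sorted grid.
    left = 0
    right = 0
    n = len(grid)
    csum = np.concatenate([[0.0], np.cumsum(mean)])
    for i, t in enumerate(grid):
        while left < n and grid[left] < t - half:
            left += 1
        while right < n and grid[right] <= t + half:
            right += 1
        smoothed[i] = (csum[right] - csum[left]) / (right - left)
    return DerivativeCurve(grid.copy(), smoothed)


def find_transitions(
    deriv: DerivativeCurve, min_prominence: float = 0.05
) -> list[Transition]:
    """Pick -dRFU/dT maxima as melting transitions.

    ``min_prominence`` is relative: a peak must have prominence of at least
    ``min_prominence * (max - min)`` of the curve. Tm is reported at the
    grid point of each maximum, sorted ascending.
    """
    y = deriv.minus_drfu_dt
    span = float(np.max(y) - np.min(y))
    if span <= 1e-12 * max(float(np.abs(y).max()), 1.0):
        return []  # numerically flat curve (e.g. pure linear decay)
    idx, props = find_peaks(y, prominence=min_prominence * span)
    return [
        Transition(float(deriv.temperatures[i]), float(y[i]), float(p))
        for i, p in zip(idx, props["prominences"])
    ]


def compare_titration(transition_sets: dict[float, list[Transition]]) -> pd.DataFrame:
    """Tabulate transitions across a MgCl2 titration.

    One row per Mg concentration (sorted ascending) listing all Tms, the
    dominant (tallest) peak, and the shift of that dominant Tm relative to
    the previous concentration — a positive trend reflects Mg-dependent
    stabilization.
    """
    if len(transition_sets) < 2:
        raise ValueError("need transition sets for at least two Mg conditions")
    rows = []
    prev_top = None
    for mg in sorted(transition_sets):
        ts = transition_sets[mg]
        if ts:
            top = max(ts, key=lambda t: t.height)
            top_tm, top_h = top.tm_C, top.height
        else:
            top_tm = top_h = np.nan
        shift = top_tm - prev_top if prev_top is not None and np.isfinite(top_tm) else np.nan
        rows.append(
            {
                "mg_mM": mg,
                "n_transitions": len(ts),
                "tms_C": ",".join(f"{t.tm_C:.2f}" for t in ts),
                "top_tm_C": top_tm,
                "top_height": top_h,
                "d_top_tm_vs_prev_C": shift,
            }
        )
        if np.isfinite(top_tm):
            prev_top = top_tm
    return pd.DataFrame(rows)


def read_melt_csv(path) -> list[MeltCurve]:
    """Read a long-format melt CSV (columns temperature, rfu, replicate)."""
    frame = pd.read_csv(path)
    required = {"temperature", "rfu", "replicate"}
    if not required.issubset(frame.columns):
        raise ValueError(f"melt CSV needs columns {sorted(required)}")
    curves = []
    for rep, sub in frame.groupby("replicate"):
        sub = sub.sort_values("temperature")
        curves.append(MeltCurve(sub["temperature"].to_numpy(), sub["rfu"].to_numpy(), int(rep)))
    return curves


class MeltTransitionDetector(BaseEstimator):
    """Replicate melt curves in, melting transitions out.

    Runs the full chain (normalize each replicate, differentiate, average,
    smooth over ``window_C`` degrees, pick peaks above ``min_prominence``
    relative prominence). Fitted attributes: ``derivative_`` (the smoothed
    averaged -dRFU/dT curve) and ``transitions_`` (list of
    :class:`Transition`).
    """

    def __init__(self, window_C: float = 1.5, min_prominence: float = 0.05, normalize: bool = True):
        self.window_C = window_C
        self.min_prominence = min_prominence
        self.normalize = normalize

    def fit(self, curves: Sequence[MeltCurve], y=None):
        if self.normalize:
            curves = [normalize_curve(c) for c in curves]
        derivs = [derivative(c) for c in curves]
        self.derivative_ = average_and_smooth(derivs, window_C=self.window_C)
        self.transitions_ = find_transitions(self.derivative_, min_prominence=self.min_prominence)
        return self
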