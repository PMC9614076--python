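"""Thresholded frame-difference movement quantification.

The core movement statistic for radar ``i`` at slow-time frame ``n`` is

    E_i[n] = sum_{k=0}^{L_signal} g_{i,n}[k]

    g_{i,n}[k] = |y_{i,n}[k] - y_{i,n-1}[k]|   if y_{i,n}[k] > T_i[k]
                 0                             otherwise

i.e. the sum over the attributed bin range of absolute consecutive-frame
amplitude differences, where each bin contributes only if the *current*
frame's amplitude exceeds a per-bin noise threshold ``T[k]``.  ``E[0]`` is
defined as 0 (there is no predecessor frame).

The per-frame series (20 values per second at the nominal frame rate) is
then averaged within each second, and seconds contaminated by caregiver
intervention are marked missing — never zeroed, which would bias both the
asymmetry ratios and the agreement statistics downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import RadarFrameSeries

__all__ = [
    "ThresholdProfile",
    "MovementSeries",
    "ExclusionIntervals",
    "estimate_threshold",
    "quantify_movement",
    "aggregate_per_second",
    "apply_exclusions",
]

logger = logging.getLogger(__name__)


@dataclass
class ThresholdProfile:
    """Per-range-bin noise threshold T[k] (frame-amplitude units)."""

    t: np.ndarray
    method: str = "quantile"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1:
            raise ValueError("threshold must be a 1-D per-bin vector")
        if np.any(self.t < 0):
            raise ValueError("thresholds must be nonnegative")


@dataclass
class MovementSeries:
    """Quantified movement E[n] at frame rate, plus 1 Hz aggregation.

    ``per_second`` is None until :func:`aggregate_per_second` runs; excluded
    seconds are NaN (missing), never silent zeros.
    """

    e: np.ndarray
    frame_rate: float
    side: str = "left"
    per_second: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        if np.any(self.e < 0):
            raise ValueError("movement values must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.e.shape[0]

    @property
    def n_seconds(self) -> int:
        if self.per_second is None:
            return 0
        return self.per_second.shape[0]


class ExclusionIntervals:
    """Caregiver-interference intervals in seconds from session start.

    Intervals are normalized (sorted, overlaps merged) on construction.
    """

    def __init__(self, intervals=()):
        norm = []
        for pair in intervals:
            try:
                start, end = float(pair[0]), float(pair[1])
            except (TypeError, ValueError, IndexError) as exc:
                raise ValueError(f"malformed interval {pair!r}") from exc
            if not start < end:
                raise ValueError(
                    f"interval start ({start}) must be < end ({end})"
                )
            if start < 0:
                raise ValueError(f"interval start ({start}) is negative")
            norm.append((start, end))
        norm.sort()
        merged: list[tuple[float, float]] = []
        for start, end in norm:
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        self.intervals: tuple[tuple[float, float], ...] = tuple(merged)

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def overlaps_second(self, s: int) -> bool:
        """True if any interval overlaps the half-open second [s, s+1)."""
        return any(start < s + 1 and end > s for start, end in self.intervals)


# ---------------------------------------------------------------------------
# threshold estimation
# ---------------------------------------------------------------------------

def estimate_threshold(
    series: RadarFrameSeries,
    method: str = "quantile",
    params: dict | None = None,
    calibration_window_s: tuple[float, float] | None = None,
) -> ThresholdProfile:
    """Estimate the per-bin noise threshold from a movement-free window.

    With ``method="quantile"`` (default), ``t[k]`` is the q-th quantile of
    the absolute amplitudes |y[n, k]| over the calibration window
    (``params["q"]``, default 0.95).  With ``method="mean_plus_c_sigma"``,
    ``t[k] = mean + c * std`` of the raw amplitudes (``params["c"]``,
    default 3), clipped at 0.  If no calibration window is given the whole
    session is used.
    """
    params = dict(params or {})
    if calibration_window_s is not None:
        start_s, end_s = calibration_window_s
        i0 = int(math.floor(start_s * series.frame_rate))
        i1 = int(math.ceil(end_s * series.frame_rate))
        window = series.frames[max(i0, 0):i1]
    else:
        window = series.frames
    if window.shape[0] == 0:
        raise ValueError("empty calibration window")
    if method == "quantile":
        q = float(params.setdefault("q", 0.95))
        t = np.quantile(np.abs(window), q, axis=0)
    elif method == "mean_plus_c_sigma":
        c = float(params.setdefault("c", 3.0))
        t = window.mean(axis=0) + c * window.std(axis=0)
        t = np.clip(t, 0.0, None)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return ThresholdProfile(t=t, method=method, params=params)


# ---------------------------------------------------------------------------
# the movement statistic
# ---------------------------------------------------------------------------

def quantify_movement(
    series: RadarFrameSeries,
    threshold: ThresholdProfile,
    l_signal: int,
) -> MovementSeries:
    """Compute E[n]: thresholded frame differences summed over bins 0..l_signal."""
    y = series.frames
    if threshold.t.shape[0] != series.n_bins:
        raise ValueError(
            f"threshold length {threshold.t.shape[0]} != n_bins {series.n_bins}"
        )
    if not 0 <= l_signal < series.n_bins:
        raise ValueError(
            f"l_signal ({l_signal}) must lie in [0, n_bins={series.n_bins})"
        )
    sub = y[:, : l_signal + 1]
    t = threshold.t[: l_signal + 1]
    diffs = np.abs(sub[1:] - sub[:-1])
    gate = sub[1:] > t  # current-frame amplitude gates the contribution
    e = np.zeros(series.n_frames)
    # cumsum accumulates bins left to right, so E is reproducible against a
    # sequential per-bin summation and exactly monotone in l_signal
    e[1:] = np.cumsum(np.where(gate, diffs, 0.0), axis=1)[:, -1]
    return MovementSeries(e=e, frame_rate=series.frame_rate, side=series.side)


def aggregate_per_second(movement: MovementSeries) -> MovementSeries:
    """Average each second's frame values; trailing partial second dropped."""
    fps = int(round(movement.frame_rate))
    if fps < 1:
        raise ValueError("frame_rate must round to at least 1 frame per second")
    n_sec = movement.n_frames // fps
    if n_sec == 0:
        raise ValueError("need at least one full second of frames")
    per_second = movement.e[: n_sec * fps].reshape(n_sec, fps).mean(axis=1)
    return replace(movement, per_second=per_second)


def apply_exclusions(
    movement: MovementSeries,
    intervals: ExclusionIntervals,
) -> MovementSeries:
    """Mark per-second values overlapping any exclusion interval as missing."""
    if movement.per_second is None:
        raise ValueError("aggregate_per_second must run before apply_exclusions")
    per_second = movement.per_second.copy()
    n_excluded = 0
    for s in range(per_second.shape[0]):
        if intervals.overlaps_second(s):
            per_second[s] = np.nan
            n_excluded += 1
    if n_excluded:
        logger.info(
            "excluded %d of %d seconds (%s side) for caregiver interference",
            n_excluded, per_second.shape[0], movement.side,
        )
    return replace(movement, per_second=per_second)
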