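"""Radar frame preprocessing: slow-time bandpass filtering and clutter removal.

The raw frame matrix ``y[n, k]`` (slow-time frame n, fast-time range bin k)
is dominated by static clutter — reflections from the cradle, walls and
bedding that are constant over slow time.  Preprocessing (i) bandpass
filters each range bin along slow time to reduce noise while retaining
respiration (~0.5-1 Hz) and brisk limb motion, and (ii) removes clutter by
background subtraction, either as the per-bin temporal mean (offline batch)
or as an exponentially weighted running background (streaming-style).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

__all__ = ["RadarFrameSeries", "ClutterModel", "bandpass_filter",
           "subtract_background"]


@dataclass
class RadarFrameSeries:
    """Amplitude matrix from one radar plus acquisition metadata.

    ``frames[n, k]`` is the received amplitude of slow-time frame ``n`` at
    fast-time range bin ``k``.  ``bin_spacing`` (meters per bin) is carried
    as annotation; all processing is index-based.
    """

    frames: np.ndarray
    frame_rate: float
    bin_spacing: float = 0.0
    side: str = "left"
    radar_index: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2:
            raise ValueError("frames must be a 2-D (n_frames x n_bins) array")
        if self.frames.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain missing/non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_bins(self) -> int:
        return self.frames.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def with_frames(self, frames: np.ndarray) -> "RadarFrameSeries":
        return replace(self, frames=frames)


@dataclass(frozen=True)
class ClutterModel:
    """Background-subtraction configuration.

    method="mean" subtracts each bin's temporal mean (batch).
    method="exponential" maintains b_n[k] = alpha*b_{n-1}[k] + (1-alpha)*y_n[k],
    initialized to the mean of the first ``warmup_frames`` frames, and
    subtracts the one-frame-lagged background b_{n-1} from y_n.
    """

    method: str = "mean"
    alpha: float = 0.98
    warmup_frames: int = 20

    def __post_init__(self) -> None:
        if self.method not in ("mean", "exponential"):
            raise ValueError(f"unknown clutter method {self.method!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.warmup_frames < 1:
            raise ValueError("warmup_frames must be >= 1")


def bandpass_filter(series: RadarFrameSeries, low_hz: float = 0.1,
                    high_hz: float = 9.0, order: int = 4) -> RadarFrameSeries:
    """Zero-phase Butterworth bandpass along slow time, per range bin.

    Forward-backward filtering (``sosfiltfilt``) keeps movement events from
    being time-shifted relative to the other modalities.  With ``low_hz > 0``
    the DC (static clutter) component is removed.  ``low_hz == 0`` degrades
    to a pure lowpass.
    """
    nyq = series.frame_rate / 2.0
    if not 0 <= low_hz < high_hz:
        raise ValueError(f"need 0 <= low_hz < high_hz, got [{low_hz}, {high_hz}]")
    if high_hz >= nyq:
        raise ValueError(
            f"high_hz ({high_hz}) must be below the Nyquist rate ({nyq})"
        )
    if low_hz == 0:
        sos = signal.butter(order, high_hz, btype="lowpass", fs=series.frame_rate,
                            output="sos")
    else:
        sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                            fs=series.frame_rate, output="sos")
    # sosfiltfilt requires n_frames > padlen
    padlen = 3 * (2 * sos.shape[0] + 1)
    if series.n_frames <= padlen:
        raise ValueError(
            f"series too short for zero-phase filtering: {series.n_frames} "
            f"frames <= filter warm-up of {padlen}"
        )
    filtered = signal.sosfiltfilt(sos, series.frames, axis=0)
    return series.with_frames(filtered)


def subtract_background(series: RadarFrameSeries,
                        model: ClutterModel | None = None) -> RadarFrameSeries:
    """Remove static clutter by subtracting a per-bin background estimate."""
    model = model or ClutterModel()
    y = series.frames
    if y.shape[0] < model.warmup_frames:
        raise ValueError(
            f"need >= warmup_frames ({model.warmup_frames}) frames, "
            f"got {y.shape[0]}"
        )
    if model.method == "mean":
        resid = y - y.mean(axis=0, keepdims=True)
    else:
        b0 = y[: model.warmup_frames].mean(axis=0)
        a = model.alpha
        # b_n = (1-a) y_n + a b_{n-1} via an order-1 IIR; zi encodes a*b0
        zi = (a * b0)[np.newaxis, :]
        b, _ = signal.lfilter([1.0 - a], [1.0, -a], y, axis=0, zi=zi)
        resid = np.empty_like(y)
        resid[0] = y[0] - b0
        resid[1:] = y[1:] - b[:-1]
    return series.with_frames(resid)
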