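"""Reference-modality movement measurement from video via CAMSHIFT.

Implements the classical Continuously Adaptive Mean Shift tracker: a
normalized hue histogram is built from an initial region of interest,
back-projected onto each new frame as a per-pixel probability, and the
search window is re-centered by mean-shift iterations on the image moments
of the back-projection, then resized from the second moments.  Pixels with
too little saturation or value carry no reliable hue and are masked out,
as is standard for hue-histogram tracking.

Per-frame centroid displacements, averaged per second, give a movement
series comparable to the radar and actigraphy series.  Two independent
trackers (one per limb blob) yield side-resolved series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.color import rgb2hsv

__all__ = ["TrackState", "init_track", "track_step", "track_sequence",
           "displacement_series"]

N_HUE_BINS = 16
SAT_MIN = 0.2
VAL_MIN = 0.1
MAX_ITER = 20
CONVERGE_PX = 0.5
MIN_WINDOW = 6


@dataclass
class TrackState:
    """CAMSHIFT tracker state after one frame.

    ``window`` is (x, y, w, h) in pixel coordinates; ``histogram`` is the
    normalized hue reference model; ``centroid`` the tracked blob center.
    ``frozen`` flags a frame where the target vanished from the search
    window (the state is carried over unchanged and the frame's measurement
    is treated as missing downstream).
    """

    window: tuple[int, int, int, int]
    histogram: np.ndarray
    centroid: tuple[float, float]
    frozen: bool = False


def _hsv_and_mask(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    hsv = rgb2hsv(frame)
    mask = (hsv[..., 1] >= SAT_MIN) & (hsv[..., 2] >= VAL_MIN)
    return hsv, mask


def _check_window(frame: np.ndarray, window: tuple[int, int, int, int]) -> None:
    x, y, w, h = window
    fh, fw = frame.shape[:2]
    if w <= 0 or h <= 0 or x < 0 or y < 0 or x + w > fw or y + h > fh:
        raise ValueError(
            f"window {window} outside frame bounds ({fw} x {fh})"
        )


def init_track(frame: np.ndarray, roi: tuple[int, int, int, int]) -> TrackState:
    """Build the reference hue histogram from an initial ROI."""
    frame = np.asarray(frame)
    _check_window(frame, roi)
    x, y, w, h = roi
    hsv, mask = _hsv_and_mask(frame)
    sub_hue = hsv[y:y + h, x:x + w, 0]
    sub_mask = mask[y:y + h, x:x + w]
    if not sub_mask.any():
        raise ValueError("ROI has no saturated pixels: no hue content to model")
    hist, _ = np.histogram(sub_hue[sub_mask], bins=N_HUE_BINS, range=(0.0, 1.0))
    hist = hist.astype(float)
    hist /= hist.sum()
    return TrackState(
        window=roi,
        histogram=hist,
        centroid=(x + w / 2.0, y + h / 2.0),
    )


def back_project(frame: np.ndarray, histogram: np.ndarray) -> np.ndarray:
    """Per-pixel probability of belonging to the reference hue model."""
    hsv, mask = _hsv_and_mask(frame)
    idx = np.minimum(
        (hsv[..., 0] * N_HUE_BINS).astype(int), N_HUE_BINS - 1
    )
    return histogram[idx] * mask


def _window_moments(prob: np.ndarray, window: tuple[int, int, int, int]):
    x, y, w, h = window
    sub = prob[y:y + h, x:x + w]
    m00 = sub.sum()
    if m00 <= 1e-12:
        return m00, None, None
    ys, xs = np.mgrid[y:y + h, x:x + w]
    cx = (sub * xs).sum() / m00
    cy = (sub * ys).sum() / m00
    return m00, cx, cy


def _clamp_window(cx: float, cy: float, w: int, h: int,
                  fw: int, fh: int) -> tuple[int, int, int, int]:
    w, h = min(w, fw), min(h, fh)
    x = int(round(cx - w / 2.0))
    y = int(round(cy - h / 2.0))
    x = min(max(x, 0), fw - w)
    y = min(max(y, 0), fh - h)
    return (x, y, w, h)


def track_step(state: TrackState, frame: np.ndarray) -> TrackState:
    """Advance the tracker by one frame.

    Mean-shift iterations run until the centroid moves less than half a
    pixel or the iteration cap is reached; the window is then re-sized from
    the second moments of the back-projection (the "continuously adaptive"
    step).  If the search window holds no back-projection mass the state is
    returned frozen.
    """
    frame = np.asarray(frame)
    fh, fw = frame.shape[:2]
    prob = back_project(frame, state.histogram)

    x, y, w, h = state.window
    cx, cy = state.centroid
    for _ in range(MAX_ITER):
        m00, ncx, ncy = _window_moments(prob, (x, y, w, h))
        if ncx is None:
            return replace(state, frozen=True)
        shift = np.hypot(ncx - cx, ncy - cy)
        cx, cy = ncx, ncy
        x, y, w, h = _clamp_window(cx, cy, w, h, fw, fh)
        if shift < CONVERGE_PX:
            break

    # adapt window size from second moments about the converged centroid
    sub = prob[y:y + h, x:x + w]
    m00 = sub.sum()
    ys, xs = np.mgrid[y:y + h, x:x + w]
    var_x = (sub * (xs - cx) ** 2).sum() / m00
    var_y = (sub * (ys - cy) ** 2).sum() / m00
    new_w = max(MIN_WINDOW, int(round(4.0 * np.sqrt(max(var_x, 0.0)))))
    new_h = max(MIN_WINDOW, int(round(4.0 * np.sqrt(max(var_y, 0.0)))))
    window = _clamp_window(cx, cy, new_w, new_h, fw, fh)
    return TrackState(window=window, histogram=state.histogram,
                      centroid=(float(cx), float(cy)), frozen=False)


def track_sequence(frames, roi: tuple[int, int, int, int]) -> list[TrackState]:
    """Track one blob through a frame sequence; state 0 is the init state."""
    it = iter(frames)
    first = next(it)
    state = init_track(first, roi)
    state = track_step(state, first)  # settle onto the blob centroid
    states = [state]
    for frame in it:
        state = track_step(state, frame)
        states.append(state)
    return states


def displacement_series(track: list[TrackState], frame_rate: float) -> np.ndarray:
    """Per-second mean centroid displacement (px/frame units).

    Displacement ``j`` is the Euclidean centroid move between frames ``j``
    and ``j+1``; second ``s`` averages displacements ``s*fps .. (s+1)*fps-1``.
    Seconds touching a frozen tracker state are missing (NaN), never zero.
    A trailing partial second is dropped.
    """
    if len(track) < 2:
        raise ValueError("need at least 2 tracked frames")
    cents = np.array([s.centroid for s in track])
    frozen = np.array([s.frozen for s in track])
    d = np.hypot(*(cents[1:] - cents[:-1]).T)
    # a displacement is unreliable if either endpoint frame was frozen
    bad = frozen[1:] | frozen[:-1]
    fps = int(round(frame_rate))
    n_sec = d.shape[0] // fps
    if n_sec == 0:
        raise ValueError("need at least one full second of tracked frames")
    per_second = d[: n_sec * fps].reshape(n_sec, fps).mean(axis=1)
    bad_sec = bad[: n_sec * fps].reshape(n_sec, fps).any(axis=1)
    per_second[bad_sec] = np.nan
    return per_second
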