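"""Synthetic dual-radar phantom of a supine infant.

Emulates the measurement setup the pipeline is built for: two impulse-radio
ultrawideband (IR-UWB) radars placed bilaterally next to a cradle, each
recording an amplitude-vs-range-bin frame 20 times per second.  A single
latent movement scenario drives three modalities at once:

* radar frame matrices (static clutter + respiration at the body-center bin
  + episodic limb-movement scatterers + Gaussian sensor noise),
* a 1 Hz actigraphy activity-count trace per ankle, and
* small RGB video frames with one colored limb blob per side, whose
  displacement follows the same latent activity.

Because all three are derived from one ground-truth event train, every
downstream stage (clutter removal, body-center localization, movement
quantification, lateralization, cross-modal agreement, tracking) can be
tested for parameter recovery without hardware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScenarioError",
    "MovementEvent",
    "Scenario",
    "VideoSim",
    "latent_activity",
    "simulate_radar",
    "simulate_actigraphy",
    "simulate_video",
    "make_session_scenario",
]

#: Range-bin spacing implied by the receiver sampling rate (annotation only;
#: all algorithms operate on bin indices).  c / (2 * 23.328 GS/s) ~ 6.4 mm.
BIN_SPACING_M = 299_792_458.0 / (2.0 * 23.328e9)

SIDES = ("left", "right")

# Deterministic sub-stream ids hung off the scenario seed, so each modality
# can be regenerated independently of the others.
_STREAM_RADAR = {"left": 0, "right": 1}
_STREAM_ACTI = {"left": 2, "right": 3}
_STREAM_VIDEO = 4
_STREAM_EVENT = {"left": 10, "right": 11}
_STREAM_SCHEDULE = 20


class ScenarioError(ValueError):
    """A scenario violates one of its invariants."""


@dataclass(frozen=True)
class MovementEvent:
    """One episodic limb movement: a scatterer near one radar.

    Parameters
    ----------
    start_s, end_s
        Event window in seconds from session start.
    bin_center
        Fast-time range bin of the limb scatterer.  Must be nearer to the
        radar than that side's body-center bin.
    amplitude
        Peak reflected amplitude (same arbitrary units as the frames).
    jitter_bins
        Maximum positional wander of the scatterer, in bins.
    """

    start_s: float
    end_s: float
    bin_center: int
    amplitude: float
    jitter_bins: int = 2

    def validate(self, duration_s: float, body_center_bin: int) -> None:
        if not self.start_s < self.end_s:
            raise ScenarioError(
                f"event start_s ({self.start_s}) must be < end_s ({self.end_s})"
            )
        if self.start_s < 0 or self.end_s > duration_s:
            raise ScenarioError(
                f"event window [{self.start_s}, {self.end_s}] outside "
                f"session [0, {duration_s}]"
            )
        if self.bin_center >= body_center_bin:
            raise ScenarioError(
                f"event bin_center ({self.bin_center}) must be nearer to the "
                f"radar than body_center_bin ({body_center_bin})"
            )
        if self.amplitude <= 0:
            raise ScenarioError("event amplitude must be positive")
        if self.jitter_bins < 0:
            raise ScenarioError("jitter_bins must be nonnegative")


@dataclass(frozen=True)
class Scenario:
    """Full description of one synthetic monitoring session."""

    duration_s: float = 60.0
    frame_rate: float = 20.0
    n_bins: int = 128
    body_center_bin: int = 40
    respiration_rate_hz: float = 0.7
    respiration_amplitude: float = 1.0
    clutter_profile: np.ndarray | None = None
    noise_sigma: float = 0.02
    left_events: tuple[MovementEvent, ...] = ()
    right_events: tuple[MovementEvent, ...] = ()
    seed: int = 0
    # actigraphy model
    actigraphy_scale: float = 25.0
    actigraphy_floor: float = 1.0
    actigraphy_log_sigma: float = 0.15
    # video model
    video_frame_rate: float = 10.0
    video_size: tuple[int, int] = (96, 96)  # (height, width)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "left_events", tuple(self.left_events)
        )
        object.__setattr__(
            self, "right_events", tuple(self.right_events)
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ScenarioError("duration_s must be positive")
        if self.frame_rate <= 0:
            raise ScenarioError("frame_rate must be positive")
        if self.n_bins <= 0:
            raise ScenarioError("n_bins must be a positive integer")
        if not 0 <= self.body_center_bin < self.n_bins:
            raise ScenarioError(
                f"body_center_bin ({self.body_center_bin}) must lie in "
                f"[0, n_bins={self.n_bins})"
            )
        if self.respiration_rate_hz <= 0:
            raise ScenarioError("respiration_rate_hz must be positive")
        if self.respiration_amplitude < 0:
            raise ScenarioError("respiration_amplitude must be nonnegative")
        if self.noise_sigma < 0:
            raise ScenarioError("noise_sigma must be nonnegative")
        n_frames_exact = self.frame_rate * self.duration_s
        if abs(n_frames_exact - round(n_frames_exact)) > 1e-6:
            raise ScenarioError(
                "frame_rate * duration_s must be an integer number of frames"
            )
        if self.clutter_profile is not None:
            prof = np.asarray(self.clutter_profile, dtype=float)
            if prof.shape != (self.n_bins,):
                raise ScenarioError(
                    f"clutter_profile must have shape ({self.n_bins},), "
                    f"got {prof.shape}"
                )
        for ev in self.left_events:
            ev.validate(self.duration_s, self.body_center_bin)
        for ev in self.right_events:
            ev.validate(self.duration_s, self.body_center_bin)

    # -- derived quantities ------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration_s))

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def events(self, side: str) -> tuple[MovementEvent, ...]:
        _check_side(side)
        return self.left_events if side == "left" else self.right_events

    def clutter(self) -> np.ndarray:
        """Per-bin static clutter amplitude (deterministic in the seed)."""
        if self.clutter_profile is not None:
            return np.asarray(self.clutter_profile, dtype=float).copy()
        # Smooth default: a few broad reflectors (cradle rails, wall) on a
        # gentle range-decay baseline.
        k = np.arange(self.n_bins)
        rng = np.random.default_rng([int(self.seed), 99])
        prof = 2.0 * np.exp(-k / (0.8 * self.n_bins))
        for _ in range(3):
            center = rng.uniform(0, self.n_bins)
            width = rng.uniform(2.0, 6.0)
            prof += rng.uniform(1.0, 4.0) * np.exp(-0.5 * ((k - center) / width) ** 2)
        return prof


def _check_side(side: str) -> None:
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")


# ---------------------------------------------------------------------------
# latent activity
# ---------------------------------------------------------------------------

def _event_envelope(scenario: Scenario, side: str, index: int,
                    event: MovementEvent) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame envelope and active-frame indices for one event.

    The envelope is a strictly positive quasi-periodic limb oscillation
    (2-3.5 Hz, typical of brisk infant limb movement).  Its random phase and
    rate come from a sub-stream keyed by (seed, side, event index) only, so
    two scenarios that differ in nothing but amplitude share envelopes
    bit-exactly — this is what makes the energy-ordering property hold
    frame by frame.
    """
    rng = np.random.default_rng(
        [int(scenario.seed), _STREAM_EVENT[side], int(index)]
    )
    f_limb = rng.uniform(2.0, 3.5)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    t = scenario.frame_times()
    active = np.nonzero((t >= event.start_s) & (t < event.end_s))[0]
    tau = t[active] - event.start_s
    env = event.amplitude * (0.55 + 0.45 * np.sin(2.0 * math.pi * f_limb * tau + phase))
    return env, active


def _event_jitter(scenario: Scenario, side: str, index: int,
                  event: MovementEvent, n_active: int) -> np.ndarray:
    """Bin-offset random walk, clipped to +/- jitter_bins (amplitude-free)."""
    if event.jitter_bins == 0 or n_active == 0:
        return np.zeros(n_active, dtype=int)
    rng = np.random.default_rng(
        [int(scenario.seed), _STREAM_EVENT[side], int(index), 1]
    )
    steps = rng.integers(-1, 2, size=n_active)
    return np.clip(np.cumsum(steps), -event.jitter_bins, event.jitter_bins)


def latent_activity(scenario: Scenario, side: str) -> np.ndarray:
    """Ground-truth per-frame movement energy for one side.

    Zero outside all event windows; nonnegative everywhere.  This is the
    series recovery tests compare against.
    """
    scenario.validate()
    _check_side(side)
    out = np.zeros(scenario.n_frames)
    for i, ev in enumerate(scenario.events(side)):
        env, active = _event_envelope(scenario, side, i, ev)
        out[active] += env
    return out


# ---------------------------------------------------------------------------
# radar
# ---------------------------------------------------------------------------

def simulate_radar(scenario: Scenario, radar_side: str):
    """Simulate one radar's slow-time x fast-time amplitude matrix.

    The matrix is clutter + a respiration term (sinusoidal amplitude
    modulation spread over +/-2 bins around the body-center bin) + the limb
    scatterers of ``radar_side``'s events + i.i.d. Gaussian noise.
    Deterministic given the scenario seed.
    """
    from .preprocess import RadarFrameSeries  # local import: avoid cycle

    scenario.validate()
    _check_side(radar_side)
    n, k = scenario.n_frames, scenario.n_bins
    t = scenario.frame_times()

    frames = np.tile(scenario.clutter(), (n, 1))

    # respiration: amplitude modulation around the body-center bin
    if scenario.respiration_amplitude > 0:
        resp = scenario.respiration_amplitude * np.sin(
            2.0 * math.pi * scenario.respiration_rate_hz * t
        )
        weights = np.array([0.25, 0.5, 1.0, 0.5, 0.25])
        for off, w in zip(range(-2, 3), weights):
            b = scenario.body_center_bin + off
            if 0 <= b < k:
                frames[:, b] += w * resp

    # limb-movement scatterers, this side's events only
    for i, ev in enumerate(scenario.events(radar_side)):
        env, active = _event_envelope(scenario, radar_side, i, ev)
        jit = _event_jitter(scenario, radar_side, i, ev, active.size)
        centers = ev.bin_center + jit
        for off, w in ((-1, 0.5), (0, 1.0), (1, 0.5)):
            bins = np.clip(centers + off, 0, k - 1)
            np.add.at(frames, (active, bins), w * env)

    if scenario.noise_sigma > 0:
        rng = np.random.default_rng(
            [int(scenario.seed), _STREAM_RADAR[radar_side]]
        )
        frames += rng.normal(0.0, scenario.noise_sigma, size=(n, k))

    return RadarFrameSeries(
        frames=frames,
        frame_rate=scenario.frame_rate,
        bin_spacing=BIN_SPACING_M,
        side=radar_side,
        radar_index=0 if radar_side == "left" else 1,
    )


# ---------------------------------------------------------------------------
# actigraphy
# ---------------------------------------------------------------------------

def simulate_actigraphy(scenario: Scenario, side: str) -> np.ndarray:
    """1 Hz ankle-actigraphy activity counts for one side.

    Each second's count is the integral of that side's latent activity over
    the second, scaled to activity-count magnitude, with a small additive
    sensor floor and multiplicative log-normal noise (activity counts are
    nonnegative and heteroscedastic).  Length = floor(duration_s).
    """
    scenario.validate()
    _check_side(side)
    fps = int(round(scenario.frame_rate))
    n_sec = int(math.floor(scenario.duration_s))
    latent = latent_activity(scenario, side)
    usable = latent[: n_sec * fps].reshape(n_sec, fps)
    integral = usable.sum(axis=1) / scenario.frame_rate  # energy-seconds
    counts = scenario.actigraphy_scale * integral + scenario.actigraphy_floor
    if scenario.actigraphy_log_sigma > 0:
        rng = np.random.default_rng([int(scenario.seed), _STREAM_ACTI[side]])
        counts = counts * np.exp(
            rng.normal(0.0, scenario.actigraphy_log_sigma, size=n_sec)
        )
    return counts


# ---------------------------------------------------------------------------
# video
# ---------------------------------------------------------------------------

@dataclass
class VideoSim:
    """Synthetic video: frames plus ground-truth blob centroid tracks."""

    frames: np.ndarray          # (n_frames, H, W, 3) uint8
    frame_rate: float
    truth: dict                 # side -> (n_frames, 2) array of (x, y)

    def __len__(self) -> int:
        return self.frames.shape[0]


_BLOB_COLOR = {"left": (230, 40, 40), "right": (40, 200, 40)}
_BACKGROUND = (60, 60, 60)
_BLOB_AXES = (9.0, 6.0)  # ellipse semi-axes in px (x, y)


def _draw_ellipse(img: np.ndarray, cx: float, cy: float,
                  ax: float, ay: float, color: tuple[int, int, int]) -> None:
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    img[mask] = color


def simulate_video(scenario: Scenario) -> VideoSim:
    """Render small RGB frames with one colored limb blob per side.

    Each blob's per-frame centroid displacement is proportional to its
    side's latent activity (resampled to the video frame rate); the heading
    performs a slow random walk, and positions are clamped so each blob
    stays inside its own half of the frame.  Ground-truth centroids are
    returned alongside the frames.
    """
    scenario.validate()
    h, w = scenario.video_size
    n_vid = int(round(scenario.video_frame_rate * scenario.duration_s))
    rng = np.random.default_rng([int(scenario.seed), _STREAM_VIDEO])

    # resample latent activity (radar frame rate) onto video frame times
    t_vid = np.arange(n_vid) / scenario.video_frame_rate
    t_radar = scenario.frame_times()
    latent = {
        side: np.interp(t_vid, t_radar, latent_activity(scenario, side))
        for side in SIDES
    }

    gain = 0.9  # px of displacement per unit latent activity
    ax_px, ay_px = _BLOB_AXES
    margin_x, margin_y = ax_px + 2, ay_px + 2
    bounds = {
        "left": (margin_x, w / 2 - margin_x, margin_y, h - margin_y),
        "right": (w / 2 + margin_x, w - margin_x, margin_y, h - margin_y),
    }
    pos = {
        "left": np.array([w * 0.25, h * 0.5]),
        "right": np.array([w * 0.75, h * 0.5]),
    }
    heading = {side: rng.uniform(0, 2 * math.pi) for side in SIDES}

    frames = np.empty((n_vid, h, w, 3), dtype=np.uint8)
    truth = {side: np.empty((n_vid, 2)) for side in SIDES}
    for f in range(n_vid):
        img = np.empty((h, w, 3), dtype=np.uint8)
        img[...] = _BACKGROUND
        for side in SIDES:
            if f > 0:
                heading[side] += rng.normal(0.0, 0.6)
                step = gain * latent[side][f]
                pos[side] = pos[side] + step * np.array(
                    [math.cos(heading[side]), math.sin(heading[side])]
                )
                lo_x, hi_x, lo_y, hi_y = bounds[side]
                pos[side][0] = min(max(pos[side][0], lo_x), hi_x)
                pos[side][1] = min(max(pos[side][1], lo_y), hi_y)
            truth[side][f] = pos[side]
            _draw_ellipse(img, pos[side][0], pos[side][1],
                          ax_px, ay_px, _BLOB_COLOR[side])
        frames[f] = img
    return VideoSim(frames=frames, frame_rate=scenario.video_frame_rate,
                    truth=truth)


# ---------------------------------------------------------------------------
# canonical study sessions
# ---------------------------------------------------------------------------

def make_session_scenario(
    seed: int,
    left_amplitude: float = 3.0,
    right_amplitude: float = 1.0,
    duration_s: float = 60.0,
    quiet_head_s: float = 5.0,
    **overrides,
) -> Scenario:
    """Build the canonical monitoring-session scenario used across tests.

    The first ``quiet_head_s`` seconds are movement-free (they serve as the
    noise-threshold calibration window).  After that, movement comes in
    bursts of 1.5-3.5 s separated by 1.5-4 s of rest; both sides share the
    same burst schedule (generalized movements involve both sides) but each
    side has its own envelope phase/rate, and the two amplitudes set the
    latent left:right energy ratio.  Defaults give a 3:1 left-dominant
    session; pass equal amplitudes for a symmetric one.
    """
    rng = np.random.default_rng([int(seed), _STREAM_SCHEDULE])
    body_center = overrides.get("body_center_bin", 40)
    left_events, right_events = [], []
    t = quiet_head_s
    i = 0
    while True:
        t += rng.uniform(1.5, 4.0)
        dur = rng.uniform(1.5, 3.5)
        if t + dur > duration_s:
            break
        for side, amp, store in (
            ("left", left_amplitude, left_events),
            ("right", right_amplitude, right_events),
        ):
            if amp > 0:
                bin_center = int(rng.integers(18, body_center - 6))
                store.append(
                    MovementEvent(start_s=t, end_s=t + dur,
                                  bin_center=bin_center, amplitude=amp,
                                  jitter_bins=2)
                )
        t += dur
        i += 1
    return Scenario(
        duration_s=duration_s,
        left_events=tuple(left_events),
        right_events=tuple(right_events),
        seed=seed,
        **overrides,
    )
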