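"""Readers and writers for the pipeline's on-disk formats.

* Radar frames: HDF5 (dataset ``frames`` with ``frame_rate``/``bin_spacing``/
  ``side`` attributes) with a CSV fallback.
* Movement series: tidy CSV (second_index, side, value, excluded); missing
  seconds serialize as empty value fields, never sentinel numbers.
* Actigraphy: ActiLife-export-style CSV (epoch timestamp + vector
  magnitude); timestamp gaps become missing values on the session clock.
* Scenario / session configuration: YAML or JSON.

All times inside the package are seconds from session start; wall-clock
timestamps exist only at this I/O boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .phantom import MovementEvent, Scenario
from .preprocess import RadarFrameSeries
from .quantify import MovementSeries

__all__ = [
    "write_frames_h5", "read_frames_h5",
    "write_frames_csv", "read_frames_csv",
    "write_movement_csv", "read_movement_csv",
    "read_actigraphy_csv", "write_actigraphy_csv",
    "scenario_from_dict", "load_scenario",
]


# ---------------------------------------------------------------------------
# radar frames
# ---------------------------------------------------------------------------

def write_frames_h5(series: RadarFrameSeries, path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("frames", data=series.frames)
        ds.attrs["frame_rate"] = series.frame_rate
        ds.attrs["bin_spacing"] = series.bin_spacing
        ds.attrs["side"] = series.side
        ds.attrs["radar_index"] = series.radar_index


def read_frames_h5(path) -> RadarFrameSeries:
    with h5py.File(path, "r") as f:
        ds = f["frames"]
        return RadarFrameSeries(
            frames=ds[()],
            frame_rate=float(ds.attrs["frame_rate"]),
            bin_spacing=float(ds.attrs.get("bin_spacing", 0.0)),
            side=str(ds.attrs.get("side", "left")),
            radar_index=int(ds.attrs.get("radar_index", 0)),
        )


def write_frames_csv(series: RadarFrameSeries, path) -> None:
    """CSV fallback: metadata on comment lines, then one row per frame."""
    with open(path, "w") as f:
        f.write(f"# frame_rate={series.frame_rate}\n")
        f.write(f"# bin_spacing={series.bin_spacing}\n")
        f.write(f"# side={series.side}\n")
        f.write(f"# radar_index={series.radar_index}\n")
        np.savetxt(f, series.frames, delimiter=",")


def read_frames_csv(path) -> RadarFrameSeries:
    meta = {}
    with open(path) as f:
        pos = f.tell()
        line = f.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = f.tell()
            line = f.readline()
        f.seek(pos)
        frames = np.loadtxt(f, delimiter=",")
    return RadarFrameSeries(
        frames=frames,
        frame_rate=float(meta.get("frame_rate", 20.0)),
        bin_spacing=float(meta.get("bin_spacing", 0.0)),
        side=meta.get("side", "left"),
        radar_index=int(meta.get("radar_index", 0)),
    )


# ---------------------------------------------------------------------------
# movement series (1 Hz, tidy)
# ---------------------------------------------------------------------------

def write_movement_csv(movement: MovementSeries, path) -> None:
    if movement.per_second is None:
        raise ValueError("movement series has no per-second values to write")
    per = movement.per_second
    df = pd.DataFrame({
        "second_index": np.arange(per.shape[0]),
        "side": movement.side,
        "value": per,
        "excluded": np.isnan(per).astype(int),
    })
    # NaN values serialize as empty fields
    df.to_csv(path, index=False)


def read_movement_csv(path, frame_rate: float = 20.0) -> MovementSeries:
    df = pd.read_csv(path)
    per = df["value"].to_numpy(dtype=float)
    excluded = df["excluded"].to_numpy(dtype=int).astype(bool)
    per = per.copy()
    per[excluded] = np.nan
    side = str(df["side"].iloc[0]) if len(df) else "left"
    return MovementSeries(e=np.array([]), frame_rate=frame_rate,
                          side=side, per_second=per)


# ---------------------------------------------------------------------------
# actigraphy
# ---------------------------------------------------------------------------

def write_actigraphy_csv(values: np.ndarray, path,
                         start: str = "2000-01-01 00:00:00") -> None:
    """ActiLife-like export: one row per 1 s epoch with vector magnitude."""
    ts = pd.date_range(start=start, periods=len(values), freq="1s")
    pd.DataFrame({"timestamp": ts, "vector_magnitude": values}).to_csv(
        path, index=False
    )


def read_actigraphy_csv(path, timestamp_col: str = "timestamp",
                        vm_col: str = "vector_magnitude") -> np.ndarray:
    """Read a 1 Hz activity-count series onto the session clock.

    Timestamp gaps are filled with NaN (missing seconds); nonmonotone
    timestamps raise with the offending line number.
    """
    df = pd.read_csv(path)
    for col in (timestamp_col, vm_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    try:
        ts = pd.to_datetime(df[timestamp_col])
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable timestamps in {path}: {exc}") from exc
    secs = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    diffs = np.diff(secs)
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        # +2: header line plus 1-based indexing of the later row
        raise ValueError(
            f"nonmonotone timestamp at line {int(bad[0]) + 3} of {path}"
        )
    vm = pd.to_numeric(df[vm_col], errors="raise").to_numpy(dtype=float)
    n = int(round(secs[-1])) + 1
    out = np.full(n, np.nan)
    out[np.round(secs).astype(int)] = vm
    return out


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------

def scenario_from_dict(cfg: dict) -> Scenario:
    cfg = dict(cfg)
    for key in ("left_events", "right_events"):
        cfg[key] = tuple(
            ev if isinstance(ev, MovementEvent) else MovementEvent(**ev)
            for ev in cfg.get(key, ())
        )
    if cfg.get("clutter_profile") is not None:
        cfg["clutter_profile"] = np.asarray(cfg["clutter_profile"], dtype=float)
    if "video_size" in cfg:
        cfg["video_size"] = tuple(cfg["video_size"])
    scenario = Scenario(**cfg)
    scenario.validate()
    return scenario


def load_scenario(path) -> Scenario:
    """Load a Scenario from a YAML or JSON file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    return scenario_from_dict(cfg)
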