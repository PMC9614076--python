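"""End-to-end session processing.

Chains the full movement-assessment pipeline for one monitoring session:

    preprocess (bandpass + clutter removal)
      -> localize (body-center bin per radar)
      -> quantify (thresholded frame differences, per-second aggregation)
      -> exclusions -> lateralize (Lt/Total, Rt/Total)
      -> agreement (CCC vs actigraphy and, optionally, video tracking)

Input is either a phantom scenario (everything synthesized from one seed)
or paths to recorded files.  All parameters and the seed are logged, and
every intermediate artifact is written as CSV/JSON next to a human-readable
report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as uio
from .agreement import AlignedPair, agreement_table, align_pair
from .lateralize import AsymmetryResult, compute_asymmetry
from .localize import estimate_body_center
from .phantom import Scenario, simulate_actigraphy, simulate_radar, simulate_video
from .preprocess import ClutterModel, RadarFrameSeries, bandpass_filter, \
    subtract_background
from .quantify import ExclusionIntervals, MovementSeries, aggregate_per_second, \
    apply_exclusions, estimate_threshold, quantify_movement
from .video_track import displacement_series, track_sequence

__all__ = ["SessionReport", "default_config", "run_pipeline"]

logger = logging.getLogger(__name__)

SIDES = ("left", "right")


def default_config() -> dict:
    """Baseline session configuration; every block is overridable."""
    return {
        "session_id": "session",
        "seed": 0,
        "preprocess": {
            "band_low_hz": 0.1,
            "band_high_hz": 9.0,
            "clutter": {"method": "mean", "alpha": 0.98, "warmup_frames": 20},
        },
        "localization": {"resp_band_hz": [0.3, 1.2]},
        "threshold": {
            "method": "quantile",
            "params": {"q": 0.95},
            "calibration_window_s": [0.0, 5.0],
        },
        "exclusions": [],
        "lateralize": {"normalize_gains": False},
        "agreement": {
            "normalization": "zscore",
            "ci_method": "fisher_simple",
            "alpha": 0.05,
        },
        "video": {"enabled": True},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class SessionReport:
    """Everything one pipeline run computed."""

    session_id: str
    config: dict
    l_signal: dict
    localization: dict  # side -> BodyCenterEstimate
    movement: dict      # side -> MovementSeries (per-second, exclusions applied)
    asymmetry: AsymmetryResult | None
    agreement: pd.DataFrame | None
    actigraphy: dict = field(default_factory=dict)
    video_series: dict = field(default_factory=dict)


def _process_radar(series: RadarFrameSeries, cfg: dict):
    pp = cfg["preprocess"]
    filtered = bandpass_filter(series, pp["band_low_hz"], pp["band_high_hz"])
    clutter = ClutterModel(**pp["clutter"])
    clean = subtract_background(filtered, clutter)

    loc = estimate_body_center(
        clean, resp_band_hz=tuple(cfg["localization"]["resp_band_hz"])
    )
    th_cfg = cfg["threshold"]
    calib = th_cfg.get("calibration_window_s")
    threshold = estimate_threshold(
        clean, method=th_cfg["method"], params=dict(th_cfg.get("params", {})),
        calibration_window_s=tuple(calib) if calib else None,
    )
    movement = quantify_movement(clean, threshold, loc.l_signal)
    movement = aggregate_per_second(movement)
    return loc, movement


def _phantom_video_series(scenario: Scenario) -> dict:
    """Track each side's blob through the synthetic video."""
    sim = simulate_video(scenario)
    h, w = scenario.video_size
    rois = {
        "left": (int(w * 0.25) - 12, int(h * 0.5) - 9, 24, 18),
        "right": (int(w * 0.75) - 12, int(h * 0.5) - 9, 24, 18),
    }
    out = {}
    for side in SIDES:
        states = track_sequence(sim.frames, rois[side])
        out[side] = displacement_series(states, sim.frame_rate)
    return out


def run_pipeline(config: dict, outdir=None) -> SessionReport:
    """Run the full chain for one session and write all artifacts.

    ``config`` must contain either a ``scenario`` block (phantom mode) or an
    ``inputs`` block with file paths (``radar_left``, ``radar_right``,
    optionally ``actigraphy_left``/``actigraphy_right``).
    """
    cfg = _merge(default_config(), config)
    session_id = cfg["session_id"]
    logger.info("session %s: config %s", session_id, cfg)

    acti: dict = {}
    video_series: dict = {}
    if "scenario" in cfg:
        scenario = (cfg["scenario"] if isinstance(cfg["scenario"], Scenario)
                    else uio.scenario_from_dict(cfg["scenario"]))
        if "seed" in config and scenario.seed != cfg["seed"]:
            import dataclasses
            scenario = dataclasses.replace(scenario, seed=cfg["seed"])
        else:
            cfg["seed"] = scenario.seed
        radars = {side: simulate_radar(scenario, side) for side in SIDES}
        acti = {side: simulate_actigraphy(scenario, side) for side in SIDES}
        if cfg["video"]["enabled"]:
            video_series = _phantom_video_series(scenario)
    elif "inputs" in cfg:
        paths = cfg["inputs"]
        radars = {}
        for side in SIDES:
            p = str(paths[f"radar_{side}"])
            radars[side] = (uio.read_frames_h5(p) if p.endswith((".h5", ".hdf5"))
                            else uio.read_frames_csv(p))
        for side in SIDES:
            key = f"actigraphy_{side}"
            if paths.get(key):
                acti[side] = uio.read_actigraphy_csv(paths[key])
    else:
        raise ValueError("config needs a 'scenario' or 'inputs' block")

    # radar chain
    localization, movement = {}, {}
    intervals = ExclusionIntervals(cfg.get("exclusions", []))
    for side in SIDES:
        try:
            loc, mov = _process_radar(radars[side], cfg)
        except ValueError as exc:
            raise RuntimeError(
                f"stage failure on {side} radar: {exc}"
            ) from exc
        movement[side] = apply_exclusions(mov, intervals)
        localization[side] = loc

    asymmetry = compute_asymmetry(
        movement["left"], movement["right"],
        normalize_gains=cfg["lateralize"]["normalize_gains"],
        session_id=session_id,
    )

    # agreement table: radar-vs-actigraphy (+ video pairs when available)
    agr_cfg = cfg["agreement"]
    pairs: list[AlignedPair] = []
    for side in SIDES:
        if side in acti:
            pairs.append(align_pair(
                movement[side], acti[side],
                normalization=agr_cfg["normalization"],
                labels=("IR-UWB", "Actigraphy", side),
            ))
        if side in video_series:
            pairs.append(align_pair(
                movement[side], video_series[side],
                normalization=agr_cfg["normalization"],
                labels=("IR-UWB", "Video", side),
            ))
        if side in acti and side in video_series:
            pairs.append(align_pair(
                acti[side], video_series[side],
                normalization=agr_cfg["normalization"],
                labels=("Actigraphy", "Video", side),
            ))
    agreement = (
        agreement_table(pairs, method=agr_cfg["ci_method"],
                        alpha=agr_cfg["alpha"], seed=cfg["seed"])
        if pairs else None
    )

    report = SessionReport(
        session_id=session_id,
        config=cfg,
        l_signal={side: localization[side].l_signal for side in SIDES},
        localization=localization,
        movement=movement,
        asymmetry=asymmetry,
        agreement=agreement,
        actigraphy=acti,
        video_series=video_series,
    )
    if outdir is not None:
        _write_artifacts(report, Path(outdir))
    return report


def _write_artifacts(report: SessionReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for side in SIDES:
        uio.write_movement_csv(report.movement[side],
                               outdir / f"movement_{side}.csv")
    loc_json = {
        side: {
            "radar": side,
            "l_signal": est.l_signal,
            "confidence": est.confidence,
            "resp_band_hz": list(est.resp_band_hz),
        }
        for side, est in report.localization.items()
    }
    (outdir / "localization.json").write_text(json.dumps(loc_json, indent=2))
    asym = report.asymmetry
    (outdir / "asymmetry.json").write_text(json.dumps({
        "session_id": asym.session_id,
        "total_left": asym.total_left,
        "total_right": asym.total_right,
        "lt_over_total_pct": asym.lt_over_total_pct,
        "rt_over_total_pct": asym.rt_over_total_pct,
        "n_seconds_used": asym.n_seconds_used,
        "defined": asym.defined,
    }, indent=2))
    if report.agreement is not None:
        report.agreement.to_csv(outdir / "agreement.csv", index=False)
    _write_text_report(report, outdir / "report.txt")


def _write_text_report(report: SessionReport, path: Path) -> None:
    asym = report.asymmetry
    lines = [
        f"Session: {report.session_id}",
        f"Seed: {report.config['seed']}",
        "",
        "Body-center localization (L_signal):",
    ]
    for side, est in report.localization.items():
        lines.append(
            f"  {side:>5}: bin {est.l_signal} (confidence {est.confidence:.3f})"
        )
    lines += [
        "",
        "Movement lateralization:",
        f"  Lt/Total: {asym.lt_over_total_pct:.1f} %",
        f"  Rt/Total: {asym.rt_over_total_pct:.1f} %",
        f"  seconds used: {asym.n_seconds_used}",
    ]
    if report.agreement is not None:
        lines += ["", "Agreement (CCC with 95% CI):"]
        for _, row in report.agreement.iterrows():
            if row["error"]:
                lines.append(f"  {row['Device']:<24} {row['Side']:<5} failed: "
                             f"{row['error']}")
            else:
                lines.append(
                    f"  {row['Device']:<24} {row['Side']:<5} "
                    f"rho_z={row['rho_z']:.4f} "
                    f"[{row['ci_low']:.4f}, {row['ci_high']:.4f}] n={row['n']}"
                )
    path.write_text("\n".join(lines) + "\n")
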