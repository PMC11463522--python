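"""Readers and writers for the pipeline's plain-text formats.

Pose tracks use the DeepLabCut export CSV dialect (three header rows:
scorer / bodyparts / coords, with x, y, likelihood per part).  Eye traces are
plain CSV (time_s, azimuth_deg, elevation_deg); stimulus schedules and ground
truth are JSON (YAML accepted for schedules/configs).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import (BODY_PARTS, Epoch, EyeTrace, PoseTrack, StimulusSchedule)

logger = logging.getLogger("gaitokr")


class PoseParseError(ValueError):
    pass


def write_pose_csv(track: PoseTrack, path, scorer: str = "gaitokr-synth") -> None:
    """Write a pose track in the DeepLabCut export dialect."""
    df = track.data.copy()
    df.columns = pd.MultiIndex.from_tuples(
        [(scorer, part, coord) for part, coord in df.columns],
        names=["scorer", "bodyparts", "coords"])
    df.to_csv(path, index_label="")


def read_pose_csv(path, frame_rate: float, px_per_mm: float,
                  aliases: dict[str, str] | None = None) -> PoseTrack:
    """Read a DeepLabCut-dialect pose CSV into a validated PoseTrack.

    ``aliases`` maps file body-part names to the canonical names
    (LF, RF, LH, RH, nose, tail_base).  Extra tracked parts are ignored with
    a log line; a missing required part is a parse error naming it.
    """
    if frame_rate <= 0 or px_per_mm <= 0:
        raise ValueError("frame_rate and px_per_mm must be > 0")
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except Exception as exc:  # malformed header
        raise PoseParseError(f"cannot parse pose CSV {path}: {exc}") from exc
    if df.columns.nlevels != 3:
        raise PoseParseError(f"{path}: expected 3 header rows "
                             "(scorer/bodyparts/coords)")
    # drop the scorer level; map aliases
    df.columns = pd.MultiIndex.from_tuples(
        [(aliases.get(part, part) if aliases else part, coord)
         for _, part, coord in df.columns],
        names=["bodyparts", "coords"])
    present = set(df.columns.get_level_values(0))
    missing = [p for p in BODY_PARTS if p not in present]
    if missing:
        raise PoseParseError(f"{path}: missing required body part(s): "
                             f"{', '.join(missing)}")
    extras = sorted(present - set(BODY_PARTS))
    if extras:
        logger.info("ignoring extra tracked parts in %s: %s", path,
                    ", ".join(extras))
    cols = pd.MultiIndex.from_product([BODY_PARTS, ("x", "y", "likelihood")],
                                      names=["bodyparts", "coords"])
    for part in BODY_PARTS:
        for coord in ("x", "y", "likelihood"):
            if (part, coord) not in df.columns:
                raise PoseParseError(f"{path}: body part {part} lacks column "
                                     f"{coord}")
    data = df[[(p, c) for p in BODY_PARTS for c in ("x", "y", "likelihood")]]
    data.columns = cols
    data = data.reset_index(drop=True).astype(float)
    if data.isna().all(axis=None):
        raise PoseParseError(f"{path}: no data rows")
    return PoseTrack(data=data, frame_rate=frame_rate, px_per_mm=px_per_mm)


def write_eye_csv(trace: EyeTrace, path) -> None:
    pd.DataFrame({"time_s": trace.time, "azimuth_deg": trace.azimuth,
                  "elevation_deg": trace.elevation}).to_csv(path, index=False)


def read_eye_csv(path, sample_rate: float | None = None) -> EyeTrace:
    """Read an eye-trace CSV; the sample rate is inferred from the time grid
    unless given."""
    df = pd.read_csv(path)
    for col in ("time_s", "azimuth_deg", "elevation_deg"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-7):
        raise ValueError(f"{path}: non-uniform sampling")
    fs = sample_rate if sample_rate is not None else 1.0 / float(np.median(dt))
    return EyeTrace(time=t, azimuth=df["azimuth_deg"].to_numpy(dtype=float),
                    elevation=df["elevation_deg"].to_numpy(dtype=float),
                    sample_rate=fs)


def write_schedule(schedule: StimulusSchedule, path) -> None:
    payload = {"assay": schedule.assay,
               "epochs": [dataclasses.asdict(e) for e in schedule.epochs]}
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=1))


def read_schedule(path) -> StimulusSchedule:
    path = Path(path)
    text = path.read_text()
    payload = (yaml.safe_load(text) if path.suffix in (".yaml", ".yml")
               else json.loads(text))
    epochs = [Epoch(**e) for e in payload["epochs"]]
    if any(e.stop <= e.start for e in epochs):
        raise ValueError(f"{path}: epoch with non-positive duration")
    starts = [e.start for e in epochs]
    if starts != sorted(starts):
        raise ValueError(f"{path}: epochs out of order")
    return StimulusSchedule(assay=payload["assay"], epochs=epochs)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, cls=_NumpyEncoder))


def read_run_annotations(path) -> list[tuple[int, int]]:
    """Optional manual straight-run annotations (start_frame, end_frame)."""
    df = pd.read_csv(path)
    for col in ("start_frame", "end_frame"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    runs = list(zip(df["start_frame"].astype(int), df["end_frame"].astype(int)))
    if any(e <= s for s, e in runs):
        raise ValueError(f"{path}: run with end_frame <= start_frame")
    return runs


def config_hash(config: dict) -> str:
    """Stable short hash of a config document, for provenance records."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    cfg = (yaml.safe_load(text) if path.suffix in (".yaml", ".yml")
           else json.loads(text))
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
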