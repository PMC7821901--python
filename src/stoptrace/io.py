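"""CSV/JSON readers and writers for the pipeline's file schemas.

All times are seconds, frames 0-based, positions cm, speeds cm/s.
Schemas (column names) are fixed here and documented in the README:

* landmark CSV: ``frame, time_s, {left_ear,right_ear,spine}_{x,y}``
* trace CSV: ``time_s`` plus one column per ``cell_id`` (ΔF/F); the
  processing variant lives in a sidecar JSON
* event CSV: ``type, onset_frame, onset_s, offset_frame, offset_s, provenance``
* valid-period CSV: ``start_s, end_s``
* cell metadata CSV: ``cell_id, cell_class, reliability_p, response_amp,
  sustained, location``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import EVENT_COLUMNS, LandmarkTrack, SpeedTrace
from .errors import InputError


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def read_config_file(path) -> dict:
    """Read a pipeline config from JSON or YAML, by extension."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def write_landmarks(track: LandmarkTrack, path) -> None:
    track.to_dataframe().to_csv(path, index=False)


def read_landmarks(path, rate_hz: float | None = None) -> LandmarkTrack:
    try:
        df = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise InputError(f"landmark file not found: {path}") from exc
    return LandmarkTrack.from_dataframe(df, rate_hz=rate_hz)


def write_speed(trace: SpeedTrace, path) -> None:
    trace.to_dataframe().to_csv(path, index=False)


def write_traces(traces: pd.DataFrame, time_s, path, variant: str = "raw") -> None:
    out = traces.copy()
    out.insert(0, "time_s", np.asarray(time_s))
    out.to_csv(path, index=False)
    write_json({"variant": variant, "n_cells": traces.shape[1]},
               Path(path).with_suffix(".meta.json"))


def read_traces(path):
    """Returns ``(traces_df, time_s, rate_hz)``."""
    try:
        df = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise InputError(f"trace file not found: {path}") from exc
    if "time_s" not in df.columns:
        raise InputError(f"trace file {path} lacks a time_s column")
    time = df.pop("time_s").to_numpy(dtype=float)
    if time.size < 2:
        raise InputError("trace file must hold at least 2 frames")
    rate = 1.0 / float(np.median(np.diff(time)))
    return df, time, rate


def write_events(events: pd.DataFrame, path) -> None:
    events.reindex(columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_valid_periods(path) -> list[tuple[float, float]]:
    try:
        df = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise InputError(f"valid-period file not found: {path}") from exc
    for col in ("start_s", "end_s"):
        if col not in df.columns:
            raise InputError(f"valid-period file {path} lacks column '{col}'")
    periods = []
    for i, rec in enumerate(df.itertuples(index=False)):
        if not (np.isfinite(rec.start_s) and np.isfinite(rec.end_s)) or rec.end_s <= rec.start_s:
            raise InputError(f"{path}, row {i}: invalid period ({rec.start_s}, {rec.end_s})")
        periods.append((float(rec.start_s), float(rec.end_s)))
    return periods


def write_cell_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, index=False)


def read_cell_metadata(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise InputError(f"cell metadata file not found: {path}") from exc
    if "cell_id" not in df.columns:
        raise InputError(f"cell metadata {path} lacks a cell_id column")
    return df
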