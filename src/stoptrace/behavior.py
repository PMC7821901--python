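"""Oriented locomotor speed and rule-based stop/start event detection.

The behavioral readout is a signed "oriented speed": the frame-to-frame
displacement of the head (ear midpoint) projected onto the body axis, the
vector pointing from a spine landmark to the point between the ears.
Positive speed is forward locomotion, negative is backward translation
(e.g. on a treadmill belt), and frames with |speed| at or below ~3 cm/s are
immobility.  Stops, long stops and starts are maximal-segment transitions
between those states subject to minimum-duration and speed criteria.

All detectors operate at frame resolution; duration thresholds are
converted to whole frames with round-half-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import frames_from_seconds, periods_to_mask, run_segments
from .errors import InputError

STATE_FORWARD = "forward"
STATE_BACKWARD = "backward"
STATE_STATIONARY = "stationary"
STATES = (STATE_FORWARD, STATE_BACKWARD, STATE_STATIONARY)

EVENT_STOP = "stop"
EVENT_LONG_STOP = "long_stop"
EVENT_START = "start"
EVENT_GROOMING = "grooming"
EVENT_TYPES = (EVENT_STOP, EVENT_LONG_STOP, EVENT_START, EVENT_GROOMING)

#: Canonical column order of an event table.
EVENT_COLUMNS = ["type", "onset_frame", "onset_s", "offset_frame", "offset_s", "provenance"]

LANDMARKS = ("left_ear", "right_ear", "spine")


@dataclass
class LandmarkTrack:
    """Uniformly sampled x/y positions (cm) of the tracked body points."""

    time: np.ndarray
    left_ear: np.ndarray   # (n, 2)
    right_ear: np.ndarray  # (n, 2)
    spine: np.ndarray      # (n, 2)
    rate_hz: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in LANDMARKS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.time.size, 2):
                raise InputError(f"landmark '{name}' must have shape (n, 2)")
            setattr(self, name, arr)
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise InputError("landmark time stamps must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise InputError("landmark track must be uniformly sampled")

    @property
    def n_frames(self) -> int:
        return self.time.size

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"frame": np.arange(self.n_frames), "time_s": self.time}
        for name in LANDMARKS:
            arr = getattr(self, name)
            cols[f"{name}_x"] = arr[:, 0]
            cols[f"{name}_y"] = arr[:, 1]
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, rate_hz: float | None = None) -> "LandmarkTrack":
        missing = [c for n in LANDMARKS for c in (f"{n}_x", f"{n}_y") if c not in df]
        if missing:
            raise InputError(f"landmark table lacks columns: {missing}")
        time = df["time_s"].to_numpy(dtype=float)
        if rate_hz is None:
            if time.size < 2:
                raise InputError("cannot infer sampling rate from fewer than 2 frames")
            rate_hz = 1.0 / float(np.median(np.diff(time)))
        return cls(
            time=time,
            left_ear=df[["left_ear_x", "left_ear_y"]].to_numpy(float),
            right_ear=df[["right_ear_x", "right_ear_y"]].to_numpy(float),
            spine=df[["spine_x", "spine_y"]].to_numpy(float),
            rate_hz=float(rate_hz),
        )


@dataclass
class SpeedTrace:
    """Signed oriented speed (cm/s) with per-frame locomotor state labels."""

    time: np.ndarray
    speed: np.ndarray
    state: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.state = np.asarray(self.state)
        if not (self.time.size == self.speed.size == self.state.size):
            raise InputError("time, speed and state must have equal length")

    @property
    def n_frames(self) -> int:
        return self.speed.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "time_s": self.time,
                "speed_cms": self.speed,
                "state": self.state,
            }
        )


def classify_state(
    speed,
    forward_thresh: float = 3.0,
    backward_thresh: float = -3.0,
) -> np.ndarray:
    """Label each frame forward (> 3 cm/s), backward (< −3 cm/s) or stationary."""
    speed = np.asarray(speed, dtype=float)
    if not np.all(np.isfinite(speed)):
        raise InputError("speed contains non-finite values")
    out = np.full(speed.shape, STATE_STATIONARY, dtype="<U10")
    out[speed > forward_thresh] = STATE_FORWARD
    out[speed < backward_thresh] = STATE_BACKWARD
    return out


def oriented_speed(
    track: LandmarkTrack,
    forward_thresh: float = 3.0,
    backward_thresh: float = -3.0,
    smooth_window_s: float | None = None,
) -> SpeedTrace:
    """Signed speed of the head along the body axis.

    The body axis at each frame is the unit vector from the spine landmark to
    the ear midpoint; speed is the backward difference of the ear-midpoint
    position projected on that axis, divided by the frame interval.  The first
    frame copies the second.  Frames with a degenerate axis (ears coinciding
    with the spine point) reuse the previous frame's orientation.

    ``smooth_window_s`` optionally applies a boxcar average to the speed
    before state classification (off by default).
    """
    if track.n_frames < 2:
        raise InputError("oriented speed requires at least 2 frames")
    for name in LANDMARKS:
        if not np.all(np.isfinite(getattr(track, name))):
            raise InputError(f"landmark '{name}' contains non-finite values")

    centroid = 0.5 * (track.left_ear + track.right_ear)
    axis = centroid - track.spine
    norms = np.linalg.norm(axis, axis=1)
    ok = norms > 1e-9
    if not ok.any():
        raise InputError("body orientation is degenerate at every frame")
    unit = np.zeros_like(axis)
    unit[ok] = axis[ok] / norms[ok, None]
    # carry the previous valid orientation through degenerate frames
    last = unit[np.flatnonzero(ok)[0]]
    for i in range(unit.shape[0]):
        if ok[i]:
            last = unit[i]
        else:
            unit[i] = last

    dt = 1.0 / track.rate_hz
    disp = np.diff(centroid, axis=0)
    speed = np.empty(track.n_frames)
    speed[1:] = np.einsum("ij,ij->i", disp, unit[1:]) / dt
    speed[0] = speed[1]

    if smooth_window_s is not None and smooth_window_s > 0:
        w = max(1, frames_from_seconds(smooth_window_s, track.rate_hz))
        kern = np.ones(w) / w
        speed = np.convolve(speed, kern, mode="same")

    state = classify_state(speed, forward_thresh, backward_thresh)
    return SpeedTrace(time=track.time.copy(), speed=speed, state=state, rate_hz=track.rate_hz)


def empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "type": pd.Series(dtype=str),
            "onset_frame": pd.Series(dtype=int),
            "onset_s": pd.Series(dtype=float),
            "offset_frame": pd.Series(dtype=float),
            "offset_s": pd.Series(dtype=float),
            "provenance": pd.Series(dtype=str),
        }
    )


def _events_frame(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return empty_events()
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def _onset_in_periods(onset_s: float, mask: np.ndarray, frame: int) -> bool:
    return bool(mask[frame])


def detect_stops(
    trace: SpeedTrace,
    min_immobility: float = 0.2,
    min_run: float = 0.25,
    min_avg_run_speed: float = 5.0,
    valid_periods=None,
) -> pd.DataFrame:
    """Stops: forward→stationary transitions with qualifying run and immobility.

    A stop requires immobility lasting at least ``min_immobility`` (200 ms)
    immediately preceded by a forward run of at least ``min_run`` (250 ms)
    whose average speed exceeds ``min_avg_run_speed`` (5 cm/s).  The onset is
    the first stationary frame.  Only onsets inside ``valid_periods`` (e.g.
    treadmill-on epochs) are kept.
    """
    return _detect_offsets(
        trace,
        pre_state=STATE_FORWARD,
        post_state=STATE_STATIONARY,
        min_pre=min_run,
        min_post=min_immobility,
        min_avg_pre_speed=min_avg_run_speed,
        max_abs_pre_speed=None,
        event_type=EVENT_STOP,
        valid_periods=valid_periods,
    )


def detect_long_stops(
    trace: SpeedTrace,
    min_immobility: float = 3.0,
    min_run: float = 0.1,
    valid_periods=None,
) -> pd.DataFrame:
    """Long stops: immobility of at least 3 s after a run of at least 100 ms.

    The average-run-speed criterion of :func:`detect_stops` is deliberately
    not applied, to keep more of the rarer long events.
    """
    return _detect_offsets(
        trace,
        pre_state=STATE_FORWARD,
        post_state=STATE_STATIONARY,
        min_pre=min_run,
        min_post=min_immobility,
        min_avg_pre_speed=None,
        max_abs_pre_speed=None,
        event_type=EVENT_LONG_STOP,
        valid_periods=valid_periods,
    )


def detect_starts(
    trace: SpeedTrace,
    min_stationary: float = 0.25,
    min_locomotion: float = 0.2,
    max_pre_speed: float = 2.0,
    valid_periods=None,
) -> pd.DataFrame:
    """Starts: stationary→forward transitions.

    Requires at least ``min_stationary`` (250 ms) of immobility with mean
    absolute speed below ``max_pre_speed`` (2 cm/s), followed by at least
    ``min_locomotion`` (200 ms) of forward locomotion.  The onset is the
    first forward frame.
    """
    return _detect_offsets(
        trace,
        pre_state=STATE_STATIONARY,
        post_state=STATE_FORWARD,
        min_pre=min_stationary,
        min_post=min_locomotion,
        min_avg_pre_speed=None,
        max_abs_pre_speed=max_pre_speed,
        event_type=EVENT_START,
        valid_periods=valid_periods,
    )


def _detect_offsets(
    trace: SpeedTrace,
    pre_state: str,
    post_state: str,
    min_pre: float,
    min_post: float,
    min_avg_pre_speed: float | None,
    max_abs_pre_speed: float | None,
    event_type: str,
    valid_periods,
) -> pd.DataFrame:
    if trace.n_frames == 0:
        return empty_events()
    rate = trace.rate_hz
    f_pre = max(1, frames_from_seconds(min_pre, rate))
    f_post = max(1, frames_from_seconds(min_post, rate))
    mask = periods_to_mask(valid_periods, rate, trace.n_frames)

    segs = run_segments(trace.state)
    rows = []
    for prev, seg in zip(segs, segs[1:]):
        if seg.label != post_state or prev.label != pre_state:
            continue
        if seg.length < f_post or prev.length < f_pre:
            continue
        pre_speed = trace.speed[prev.start : prev.stop]
        if min_avg_pre_speed is not None and pre_speed.mean() <= min_avg_pre_speed:
            continue
        if max_abs_pre_speed is not None and np.abs(pre_speed).mean() >= max_abs_pre_speed:
            continue
        onset = seg.start
        if not mask[onset]:
            continue
        rows.append(
            {
                "type": event_type,
                "onset_frame": onset,
                "onset_s": trace.time[onset],
                "offset_frame": float(seg.stop - 1),
                "offset_s": trace.time[seg.stop - 1],
                "provenance": "detected",
            }
        )
    return _events_frame(rows)


def read_annotations(
    path,
    duration_s: float | None = None,
    rate_hz: float | None = None,
) -> pd.DataFrame:
    """Read manually scored events (type, onset_s[, offset_s]) from a CSV.

    Rows are validated one by one so malformed input fails with its row
    number.  Events are tagged ``provenance='annotated'``.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        if isinstance(exc, FileNotFoundError):
            raise InputError(f"annotation file not found: {path}") from exc
        return empty_events()
    if df.empty:
        return empty_events()
    for col in ("type", "onset_s"):
        if col not in df.columns:
            raise InputError(f"annotation file {path} lacks required column '{col}'")

    rows = []
    for i, rec in enumerate(df.itertuples(index=False)):
        etype = str(rec.type)
        if etype not in EVENT_TYPES:
            raise InputError(f"{path}, row {i}: unknown event type '{etype}'")
        try:
            onset = float(rec.onset_s)
        except (TypeError, ValueError) as exc:
            raise InputError(f"{path}, row {i}: onset_s is not numeric") from exc
        if not np.isfinite(onset) or onset < 0:
            raise InputError(f"{path}, row {i}: onset_s must be finite and >= 0")
        if duration_s is not None and onset >= duration_s:
            raise InputError(
                f"{path}, row {i}: onset {onset:.3f} s beyond recording end {duration_s:.3f} s"
            )
        offset = getattr(rec, "offset_s", np.nan)
        offset = float(offset) if offset is not None else np.nan
        if np.isfinite(offset):
            if offset < onset:
                raise InputError(f"{path}, row {i}: offset_s precedes onset_s")
            if duration_s is not None and offset > duration_s:
                raise InputError(f"{path}, row {i}: offset_s beyond recording end")
        frame = int(round(onset * rate_hz)) if rate_hz else -1
        off_frame = int(round(offset * rate_hz)) if (rate_hz and np.isfinite(offset)) else np.nan
        rows.append(
            {
                "type": etype,
                "onset_frame": frame,
                "onset_s": onset,
                "offset_frame": off_frame,
                "offset_s": offset,
                "provenance": "annotated",
            }
        )
    out = _events_frame(rows)
    return out.sort_values("onset_s", kind="stable").reset_index(drop=True)
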