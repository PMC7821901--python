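"""Coupled behavior + calcium simulator with planted ground truth.

The generator emulates the structure of a micro-endoscopic recording in a
freely moving mouse: episodic forward locomotion bouts interleaved with
immobility (some of it spent grooming), a landmark track (two ears and a
spine point) whose oriented speed reproduces the simulated speed profile,
and 20 Hz GCaMP6s-like ΔF/F traces from planted cell classes
(stop-excited with event-wise reliability, stop-inhibited, start-excited,
grooming-excited, uncorrelated).

Calcium traces are built as Poisson event trains drawn from a per-cell rate,
convolved with a difference-of-exponentials kernel
``k(t) = exp(-t/tau_d) - exp(-t/tau_r)`` (rise 75 ms, decay 500 ms)
normalized to unit peak, plus white Gaussian noise.  Ground-truth event
onsets are recorded on the emitted speed trace itself, so clean traces
round-trip exactly through the detectors in :mod:`stoptrace.behavior`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import frames_from_seconds, run_segments
from .behavior import (
    EVENT_COLUMNS,
    EVENT_GROOMING,
    EVENT_LONG_STOP,
    EVENT_START,
    EVENT_STOP,
    STATE_FORWARD,
    STATE_STATIONARY,
    LandmarkTrack,
    SpeedTrace,
    classify_state,
)
from .errors import InputError

STATE_GROOMING = "grooming"

CELL_CLASSES = (
    "stop_excited",
    "stop_inhibited",
    "start_excited",
    "grooming_excited",
    "uncorrelated",
)

#: event type whose onsets a cell class responds to
_PREFERRED_EVENT = {
    "stop_excited": EVENT_STOP,
    "stop_inhibited": EVENT_STOP,
    "start_excited": EVENT_START,
    "grooming_excited": EVENT_GROOMING,
}

#: duration of the suppression of tonic activity in inhibited cells (s)
SUPPRESSION_S = 1.25

#: geometry of the synthetic animal (cm)
EAR_SEPARATION_CM = 1.0
SPINE_OFFSET_CM = 2.0


@dataclass(frozen=True)
class DurationSpec:
    """Mean/min/max of a duration distribution (truncated shifted exponential)."""

    mean: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (0 < self.min <= self.mean <= self.max):
            raise InputError(
                f"require 0 < min <= mean <= max, got {self.mean}/{self.min}/{self.max}"
            )

    def draw(self, rng: np.random.Generator) -> float:
        if self.max == self.min:
            return float(self.min)
        scale = self.mean - self.min
        if scale <= 0:
            return float(rng.uniform(self.min, self.max))
        for _ in range(200):
            x = self.min + rng.exponential(scale)
            if x <= self.max:
                return float(x)
        return float(self.max)

    def to_dict(self) -> dict:
        return {"mean": self.mean, "min": self.min, "max": self.max}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated session.

    Durations are in seconds, speeds in cm/s, amplitudes in ΔF/F units.
    ``quantal_amp`` is the ΔF/F contribution of a single Poisson event
    (a "spike"); a planted response of amplitude ``a`` is realized as an
    expected ``a / quantal_amp`` events spread over ``response_duration_s``.
    """

    duration_s: float = 600.0
    behavior_rate_hz: float = 20.0
    calcium_rate_hz: float = 20.0
    bout_duration_s: DurationSpec = field(default_factory=lambda: DurationSpec(4.0, 1.0, 15.0))
    immobility_duration_s: DurationSpec = field(default_factory=lambda: DurationSpec(1.5, 0.5, 8.0))
    bout_prob: float = 1.0
    grooming_prob: float = 0.15
    run_speed_cms: float = 12.0
    speed_ramp_s: float = 0.1
    noise_sd: float = 0.1
    quantal_amp: float = 0.05
    response_duration_s: float = 0.2
    spontaneous_bump_rate_hz: float = 0.1
    kernel_rise_s: float = 0.075
    kernel_decay_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise InputError("duration_s must be positive")
        if self.behavior_rate_hz not in (20.0, 50.0, 20, 50):
            raise InputError("behavior_rate_hz must be 20 or 50")
        if self.calcium_rate_hz != 20.0 and self.calcium_rate_hz != 20:
            raise InputError("calcium_rate_hz must be 20")
        if not 0.0 <= self.grooming_prob <= 1.0:
            raise InputError("grooming_prob must lie in [0, 1]")
        if not 0.0 <= self.bout_prob <= 1.0:
            raise InputError("bout_prob must lie in [0, 1]")
        if not 0 < self.kernel_rise_s < self.kernel_decay_s:
            raise InputError("require kernel_decay_s > kernel_rise_s > 0")
        for name in ("run_speed_cms", "noise_sd", "quantal_amp", "response_duration_s"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be nonnegative")

    def to_dict(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            d[k] = v.to_dict() if isinstance(v, DurationSpec) else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("bout_duration_s", "immobility_duration_s"):
            if key in d and isinstance(d[key], dict):
                d[key] = DurationSpec(**d[key])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruthCell:
    """A planted cell: class, event-wise reliability and response amplitude."""

    cell_id: str
    cell_class: str
    reliability_p: float = 0.6
    response_amp: float = 0.5
    sustained: bool = False
    location: str = "medial"
    baseline_rate: float | None = None  # tonic rate (a.u./s); class default if None

    def __post_init__(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise InputError(f"unknown cell class '{self.cell_class}'")
        if not 0.0 <= self.reliability_p <= 1.0:
            raise InputError("reliability_p must lie in [0, 1]")
        if self.response_amp < 0:
            raise InputError("response_amp must be nonnegative")
        if self.location not in ("medial", "lateral"):
            raise InputError("location must be 'medial' or 'lateral'")

    @property
    def resolved_baseline_rate(self) -> float:
        if self.baseline_rate is not None:
            return self.baseline_rate
        return 1.5 if self.cell_class == "stop_inhibited" else 0.1


@dataclass
class BehaviorSchedule:
    """Ordered behavioral intervals tiling [0, duration] plus ground-truth events."""

    intervals: pd.DataFrame  # columns state, start_s, end_s
    events: pd.DataFrame     # EVENT_COLUMNS, provenance='ground_truth'
    duration_s: float
    rate_hz: float

    def onsets(self, event_type: str) -> np.ndarray:
        sel = self.events[self.events["type"] == event_type]
        return sel["onset_s"].to_numpy(dtype=float)

    def event_table(self, event_type: str) -> pd.DataFrame:
        return self.events[self.events["type"] == event_type].reset_index(drop=True)


def _build_intervals(config: SimulationConfig, rng: np.random.Generator) -> list[list]:
    """Alternating forward/stationary intervals; always ends stationary."""
    dur = config.duration_s
    intervals: list[list] = []  # [state, start, end]
    t = 0.0
    placed_bout = False
    while True:
        has_bout = config.bout_prob > 0 and rng.random() < config.bout_prob
        d_b = config.bout_duration_s.draw(rng) if has_bout else 0.0
        d_i = config.immobility_duration_s.draw(rng)
        if t + d_b + d_i > dur:
            break
        if d_b > 0:
            intervals.append([STATE_FORWARD, t, t + d_b])
            placed_bout = True
        t += d_b
        if intervals and intervals[-1][0] == STATE_STATIONARY:
            intervals[-1][2] = t + d_i
        else:
            intervals.append([STATE_STATIONARY, t, t + d_i])
        t += d_i
    if not intervals:
        raise InputError(
            f"duration {dur} s too short for a single bout/immobility pair"
        )
    if config.bout_prob == 1.0 and not placed_bout:
        raise InputError(f"duration {dur} s too short to place a single bout")
    # stretch the trailing stationary interval to the recording end
    intervals[-1][2] = dur
    return intervals


def _insert_grooming(intervals: list[list], config: SimulationConfig,
                     rng: np.random.Generator) -> list[list]:
    """Grooming occupies the middle half of some stationary intervals.

    Grooming and locomotion are mutually exclusive, so grooming only ever
    replaces part of a stationary interval (of at least 1 s).
    """
    out: list[list] = []
    for state, start, end in intervals:
        d = end - start
        if (
            state == STATE_STATIONARY
            and d >= 1.0
            and rng.random() < config.grooming_prob
        ):
            g0, g1 = start + 0.25 * d, start + 0.75 * d
            out.append([STATE_STATIONARY, start, g0])
            out.append([STATE_GROOMING, g0, g1])
            out.append([STATE_STATIONARY, g1, end])
        else:
            out.append([state, start, end])
    return out


def _speed_profile(intervals, config: SimulationConfig, n_frames: int):
    """Frame-resolved oriented speed via exact-path integration.

    Speed is ``run_speed`` within forward intervals with 100 ms linear on/off
    ramps.  The head position is the time integral of that profile (computed
    on a 20× finer grid); the per-frame speed is the backward difference of
    position, i.e. exactly what :func:`stoptrace.behavior.oriented_speed`
    measures on the emitted landmark track.
    """
    rate = config.behavior_rate_hz
    fine = 20
    n_fine = n_frames * fine
    t_fine = np.arange(n_fine) / (rate * fine)
    v_fine = np.zeros(n_fine)
    for state, start, end in intervals:
        if state != STATE_FORWARD:
            continue
        ramp = min(config.speed_ramp_s, 0.5 * (end - start))
        sel = (t_fine >= start) & (t_fine < end)
        ts = t_fine[sel]
        prof = np.minimum.reduce(
            [np.ones_like(ts), (ts - start) / ramp, (end - ts) / ramp]
        )
        v_fine[sel] = config.run_speed_cms * np.clip(prof, 0.0, 1.0)
    # cumulative trapezoid position on the fine grid
    dt_fine = 1.0 / (rate * fine)
    x_fine = np.concatenate(([0.0], np.cumsum(0.5 * (v_fine[1:] + v_fine[:-1]) * dt_fine)))
    x = x_fine[::fine][:n_frames]
    speed = np.empty(n_frames)
    speed[1:] = np.diff(x) * rate
    speed[0] = speed[1] if n_frames > 1 else 0.0
    return speed, x


def _ground_truth_events(intervals, speed: np.ndarray, rate: float) -> pd.DataFrame:
    """Stops/long-stops/starts read off the emitted speed trace; grooming
    onsets from the schedule.

    A transition only counts when its flanking trace segments intersect the
    corresponding scheduled intervals: the sub-threshold ramp frames at the
    very start of the recording's first bout, for example, are not scheduled
    immobility and must not spawn a ground-truth start.
    """
    n = speed.size
    sched_forward = np.zeros(n, dtype=bool)
    t = np.arange(n) / rate
    for st, start, end in intervals:
        if st == STATE_FORWARD:
            sched_forward |= (t >= start) & (t < end)
    sched_immobile = ~sched_forward
    state = classify_state(speed)
    segs = run_segments(state)
    long_f = frames_from_seconds(3.0, rate)
    rows = []
    for prev, seg in zip(segs, segs[1:]):
        if prev.label == STATE_FORWARD and seg.label == STATE_STATIONARY:
            if not sched_immobile[seg.start : seg.stop].any():
                continue
            base = {
                "onset_frame": seg.start,
                "onset_s": seg.start / rate,
                "offset_frame": float(seg.stop - 1),
                "offset_s": (seg.stop - 1) / rate,
                "provenance": "ground_truth",
            }
            rows.append({"type": EVENT_STOP, **base})
            if seg.length >= long_f:
                rows.append({"type": EVENT_LONG_STOP, **base})
        elif prev.label == STATE_STATIONARY and seg.label == STATE_FORWARD:
            if not sched_immobile[prev.start : prev.stop].any():
                continue
            rows.append(
                {
                    "type": EVENT_START,
                    "onset_frame": seg.start,
                    "onset_s": seg.start / rate,
                    "offset_frame": float(seg.stop - 1),
                    "offset_s": (seg.stop - 1) / rate,
                    "provenance": "ground_truth",
                }
            )
    for st, start, end in intervals:
        if st == STATE_GROOMING:
            f0 = int(round(start * rate))
            rows.append(
                {
                    "type": EVENT_GROOMING,
                    "onset_frame": f0,
                    "onset_s": start,
                    "offset_frame": float(int(round(end * rate)) - 1),
                    "offset_s": end,
                    "provenance": "ground_truth",
                }
            )
    if not rows:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return df.sort_values(["onset_s", "type"], kind="stable").reset_index(drop=True)


def simulate_behavior(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Simulate one session's behavior.

    Returns ``(schedule, speed_trace, landmark_track)``.  The landmark track
    places the animal on a straight path with the head (ear midpoint) at the
    integrated position, ears 1 cm apart, and the spine point 2 cm behind the
    ear midpoint along the heading, so the oriented-speed computation
    reproduces the schedule's speed exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rate = config.behavior_rate_hz
    n_frames = int(round(config.duration_s * rate))
    if n_frames < 2:
        raise InputError("duration too short for a behavior trace")

    intervals = _build_intervals(config, rng)
    intervals = _insert_grooming(intervals, config, rng)
    speed, x = _speed_profile(intervals, config, n_frames)
    events = _ground_truth_events(intervals, speed, rate)

    schedule = BehaviorSchedule(
        intervals=pd.DataFrame(intervals, columns=["state", "start_s", "end_s"]),
        events=events,
        duration_s=config.duration_s,
        rate_hz=rate,
    )
    time = np.arange(n_frames) / rate
    trace = SpeedTrace(time=time, speed=speed, state=classify_state(speed), rate_hz=rate)

    heading = np.array([1.0, 0.0])
    normal = np.array([0.0, 1.0])
    ear_mid = np.column_stack([x, np.zeros(n_frames)])
    track = LandmarkTrack(
        time=time,
        left_ear=ear_mid + 0.5 * EAR_SEPARATION_CM * normal,
        right_ear=ear_mid - 0.5 * EAR_SEPARATION_CM * normal,
        spine=ear_mid - SPINE_OFFSET_CM * heading,
        rate_hz=rate,
    )
    return schedule, trace, track


def simulate_cell_rate(
    schedule: BehaviorSchedule,
    cell: GroundTruthCell,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Underlying activity rate (a.u./s) of one planted cell on the calcium clock.

    For each preferred event the cell responds with probability
    ``reliability_p``: excited classes add a rate bump whose time-integral is
    ``response_amp`` (extended through the behavioral state when
    ``sustained``); the stop-inhibited class carries a tonic baseline that is
    suppressed to zero for 1.25 s (or through the state).  Uncorrelated cells
    receive event-independent random bumps.
    """
    cal = config.calcium_rate_hz
    n = int(round(schedule.duration_s * cal))
    rate = np.full(n, cell.resolved_baseline_rate, dtype=float)
    amp_rate = (
        cell.response_amp / config.response_duration_s
        if config.response_duration_s > 0
        else 0.0
    )
    resp_f = max(1, int(round(config.response_duration_s * cal)))

    if cell.cell_class in _PREFERRED_EVENT:
        table = schedule.event_table(_PREFERRED_EVENT[cell.cell_class])
        for rec in table.itertuples(index=False):
            if rng.random() >= cell.reliability_p:
                continue
            f0 = int(round(rec.onset_s * cal))
            if cell.sustained and np.isfinite(rec.offset_s):
                f1 = int(round(rec.offset_s * cal)) + 1
            elif cell.cell_class == "stop_inhibited":
                f1 = f0 + int(round(SUPPRESSION_S * cal))
            else:
                f1 = f0 + resp_f
            f0c, f1c = max(0, f0), min(n, max(f0 + 1, f1))
            if f0c >= n:
                continue
            if cell.cell_class == "stop_inhibited":
                rate[f0c:f1c] = 0.0
            else:
                rate[f0c:f1c] += amp_rate
    else:  # uncorrelated: event-independent spontaneous bumps
        n_bumps = rng.poisson(config.spontaneous_bump_rate_hz * schedule.duration_s)
        if cell.response_amp > 0:
            for t0 in np.sort(rng.uniform(0.0, schedule.duration_s, n_bumps)):
                f0 = int(round(t0 * cal))
                rate[f0 : min(n, f0 + resp_f)] += amp_rate
    return rate


def calcium_kernel(
    rate_hz: float = 20.0,
    rise_s: float = 0.075,
    decay_s: float = 0.5,
    eps: float = 1e-12,
) -> np.ndarray:
    """Unit-peak difference-of-exponentials kernel sampled at ``rate_hz``.

    Normalization uses the analytic continuous peak, so a sampled single
    transient matches the closed form exactly at the frame times.
    """
    if not 0 < rise_s < decay_s:
        raise InputError("require decay_s > rise_s > 0")
    t_peak = math.log(decay_s / rise_s) / (1.0 / rise_s - 1.0 / decay_s)
    peak = math.exp(-t_peak / decay_s) - math.exp(-t_peak / rise_s)
    # support until the decay term falls below eps relative to the peak
    t_max = -decay_s * math.log(eps * peak)
    n = int(math.ceil(t_max * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    return (np.exp(-t / decay_s) - np.exp(-t / rise_s)) / peak


def events_to_calcium(amplitudes, config: SimulationConfig) -> np.ndarray:
    """Deterministic part of the forward model: event train → ΔF/F trace."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    kernel = calcium_kernel(
        config.calcium_rate_hz, config.kernel_rise_s, config.kernel_decay_s
    )
    return np.convolve(amplitudes, kernel)[: amplitudes.size]


def rate_to_calcium(
    rate,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
) -> np.ndarray:
    """Poisson events drawn from ``rate``, convolved with the unit-peak kernel,
    plus white Gaussian noise, sampled at the calcium rate."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise InputError("rate must be nonnegative everywhere")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if noise_sd is None:
        noise_sd = config.noise_sd
    dt = 1.0 / config.calcium_rate_hz
    q = config.quantal_amp
    counts = rng.poisson(rate / q * dt) if q > 0 else np.zeros_like(rate)
    trace = events_to_calcium(q * counts, config)
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, trace.size)
    return trace


def make_cohort(
    n_cells: int = 20,
    fractions: dict | None = None,
    reliability_p: float = 0.6,
    response_amp: float = 0.5,
    sustained: bool = False,
    seed: int = 0,
) -> list[GroundTruthCell]:
    """Build a planted cohort with the given class fractions.

    Counts use largest-remainder rounding so they sum to ``n_cells``;
    implant locations alternate medial/lateral.
    """
    if fractions is None:
        fractions = {"stop_excited": 0.5, "stop_inhibited": 0.25, "uncorrelated": 0.25}
    if n_cells < 1:
        raise InputError("n_cells must be >= 1")
    total = sum(fractions.values())
    if not math.isclose(total, 1.0, rel_tol=1e-6):
        raise InputError(f"class fractions must sum to 1, got {total}")
    raw = {c: f * n_cells for c, f in fractions.items()}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    leftover = n_cells - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:leftover]:
        counts[c] += 1
    cells = []
    i = 0
    for cls in CELL_CLASSES:
        for _ in range(counts.get(cls, 0)):
            cells.append(
                GroundTruthCell(
                    cell_id=f"cell_{i:03d}",
                    cell_class=cls,
                    reliability_p=reliability_p,
                    response_amp=response_amp,
                    sustained=sustained,
                    location="medial" if i % 2 == 0 else "lateral",
                )
            )
            i += 1
    return cells


@dataclass
class SimulatedDataset:
    """Everything one simulated session produces, with its ground truth."""

    config: SimulationConfig
    cells: list[GroundTruthCell]
    schedule: BehaviorSchedule
    speed: SpeedTrace
    landmarks: LandmarkTrack
    traces: pd.DataFrame          # time_s index implicit; columns = cell ids
    trace_time: np.ndarray
    metadata: pd.DataFrame        # one row per cell

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]


def simulate_dataset(
    config: SimulationConfig,
    cells: list[GroundTruthCell] | None = None,
) -> SimulatedDataset:
    """Simulate a full session: behavior plus one ΔF/F trace per planted cell.

    Randomness is split into independent child streams (one for behavior,
    one per cell) derived from ``config.seed``, so the dataset is
    byte-deterministic for a fixed config.
    """
    if cells is None:
        cells = make_cohort(seed=config.seed)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(cells) + 1)
    schedule, speed, track = simulate_behavior(config, np.random.default_rng(children[0]))

    n_cal = int(round(config.duration_s * config.calcium_rate_hz))
    t_cal = np.arange(n_cal) / config.calcium_rate_hz
    columns = {}
    for cell, child in zip(cells, children[1:]):
        rng = np.random.default_rng(child)
        rate = simulate_cell_rate(schedule, cell, config, rng)
        columns[cell.cell_id] = rate_to_calcium(rate, config, rng)
    traces = pd.DataFrame(columns)
    metadata = pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "cell_class": c.cell_class,
                "reliability_p": c.reliability_p,
                "response_amp": c.response_amp,
                "sustained": c.sustained,
                "location": c.location,
            }
            for c in cells
        ]
    )
    return SimulatedDataset(
        config=config,
        cells=list(cells),
        schedule=schedule,
        speed=speed,
        landmarks=track,
        traces=traces,
        trace_time=t_cal,
        metadata=metadata,
    )
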