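"""Peri-event statistics: triggered averages, shuffle test, activation probability.

The central inference is a per-cell resampling test: the maximum and minimum
of the event-triggered average within a 1.5 s window starting 0.25 s before
the event are compared with the same statistics recomputed after drawing the
same number of pseudo-event times uniformly within the analyzed periods,
1000 times.  A cell is called excited when its observed maximum strictly
exceeds the 95th percentile of the shuffled maxima, and inhibited when its
observed minimum falls strictly below the 5th percentile of the shuffled
minima (two one-sided calls at 5%, matching separate excited/inhibited
categories; ties are never significant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import frames_from_seconds, periods_to_mask
from .errors import InputError

__all__ = [
    "EventWindow",
    "EventAverage",
    "ResamplingResult",
    "event_triggered_average",
    "resampling_test",
    "activation_probability",
    "per_event_peaks",
    "kinematic_correlation",
    "stop_kinematics",
]


@dataclass(frozen=True)
class EventWindow:
    """Analysis window: ``length_s`` seconds beginning ``pre_s`` before onset."""

    pre_s: float = 0.25
    length_s: float = 1.5

    def __post_init__(self) -> None:
        if not 0 <= self.pre_s < self.length_s:
            raise InputError("require 0 <= pre_s < length_s")

    def frames(self, rate_hz: float) -> tuple[int, int]:
        return (
            frames_from_seconds(self.pre_s, rate_hz),
            max(1, frames_from_seconds(self.length_s, rate_hz)),
        )


#: extended window for sustained grooming activity
GROOMING_WINDOW = EventWindow(pre_s=0.25, length_s=4.25)


@dataclass
class EventAverage:
    window: EventWindow
    time: np.ndarray        # seconds relative to onset
    mean: np.ndarray
    sem: np.ndarray
    n_events: int
    n_dropped: int
    peak: float
    trough: float
    time_to_peak_s: float
    sem_defined: bool


def _usable_onsets(onsets, pre_f: int, len_f: int, n_frames: int):
    onsets = np.asarray(onsets, dtype=int)
    start = onsets - pre_f
    ok = (start >= 0) & (start + len_f <= n_frames)
    return onsets[ok], int((~ok).sum())


def _event_matrix(values: np.ndarray, onsets: np.ndarray, pre_f: int, len_f: int):
    idx = (onsets[:, None] - pre_f) + np.arange(len_f)[None, :]
    return values[idx]


def event_triggered_average(
    values,
    rate_hz: float,
    onset_frames,
    window: EventWindow = EventWindow(),
) -> EventAverage:
    """Mean ± SEM trace across events, with peak/trough/time-to-peak.

    Events whose window is not fully inside the recording are dropped and
    counted in ``n_dropped``.  With a single usable event the SEM is
    undefined and flagged.
    """
    values = np.asarray(values, dtype=float)
    pre_f, len_f = window.frames(rate_hz)
    onsets, n_dropped = _usable_onsets(onset_frames, pre_f, len_f, values.size)
    if onsets.size == 0:
        raise InputError("no event has a full analysis window inside the recording")
    seg = _event_matrix(values, onsets, pre_f, len_f)
    mean = seg.mean(axis=0)
    if onsets.size >= 2:
        sem = seg.std(axis=0, ddof=1) / np.sqrt(onsets.size)
        sem_defined = True
    else:
        sem = np.full(len_f, np.nan)
        sem_defined = False
    rel_t = (np.arange(len_f) - pre_f) / rate_hz
    ipk = int(np.argmax(mean))
    return EventAverage(
        window=window,
        time=rel_t,
        mean=mean,
        sem=sem,
        n_events=int(onsets.size),
        n_dropped=n_dropped,
        peak=float(mean[ipk]),
        trough=float(mean.min()),
        time_to_peak_s=float(rel_t[ipk]),
        sem_defined=sem_defined,
    )


@dataclass
class ResamplingResult:
    observed_max: float
    observed_min: float
    shuffled_max: np.ndarray
    shuffled_min: np.ndarray
    excited: bool
    inhibited: bool
    n_events: int
    n_shuffles: int
    alpha: float
    low_n: bool
    #: percent of shuffles whose max lies strictly below the observed max
    max_percentile: float
    #: percent of shuffles whose min lies strictly above the observed min
    min_percentile: float
    #: exceedance of the observed max over the null mean, in null SDs
    z_max: float = 0.0
    #: exceedance of the observed min below the null mean, in null SDs
    z_min: float = 0.0


def resampling_test(
    values,
    rate_hz: float,
    onset_frames,
    window: EventWindow = EventWindow(),
    valid_periods=None,
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    split_alpha: bool = False,
    _chunk: int = 250,
) -> ResamplingResult:
    """Shuffle-based significance of peri-event excitation/inhibition.

    Each shuffle draws ``len(onset_frames)`` pseudo-onsets uniformly among
    the frames of ``valid_periods`` whose full window fits in the recording,
    recomputes the event-average max and min, and the observed statistics
    are compared with the type-7 quantiles of those null distributions
    (strict inequality; ``split_alpha`` uses alpha/2 per tail instead).
    """
    if n_shuffles < 100:
        raise InputError("n_shuffles must be at least 100")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    values = np.asarray(values, dtype=float)
    pre_f, len_f = window.frames(rate_hz)
    onsets, _ = _usable_onsets(onset_frames, pre_f, len_f, values.size)
    if onsets.size == 0:
        raise InputError("no usable events for the resampling test")

    mask = periods_to_mask(valid_periods, rate_hz, values.size)
    if valid_periods is not None:
        longest = max(end - start for start, end in valid_periods)
        if longest < window.length_s:
            raise InputError("every valid period is shorter than the analysis window")
    allowed = np.flatnonzero(mask)
    allowed = allowed[(allowed - pre_f >= 0) & (allowed - pre_f + len_f <= values.size)]
    if allowed.size == 0:
        raise InputError("no allowed pseudo-onset frames within valid periods")

    obs = _event_matrix(values, onsets, pre_f, len_f).mean(axis=0)
    observed_max, observed_min = float(obs.max()), float(obs.min())

    smax = np.empty(n_shuffles)
    smin = np.empty(n_shuffles)
    done = 0
    while done < n_shuffles:
        k = min(_chunk, n_shuffles - done)
        pseudo = rng.choice(allowed, size=(k, onsets.size), replace=True)
        seg = values[(pseudo[:, :, None] - pre_f) + np.arange(len_f)[None, None, :]]
        means = seg.mean(axis=1)
        smax[done : done + k] = means.max(axis=1)
        smin[done : done + k] = means.min(axis=1)
        done += k
    tail = alpha / 2 if split_alpha else alpha
    excited = observed_max > np.quantile(smax, 1.0 - tail)
    inhibited = observed_min < np.quantile(smin, tail)
    return ResamplingResult(
        observed_max=observed_max,
        observed_min=observed_min,
        shuffled_max=smax,
        shuffled_min=smin,
        excited=bool(excited),
        inhibited=bool(inhibited),
        n_events=int(onsets.size),
        n_shuffles=n_shuffles,
        alpha=alpha,
        low_n=onsets.size < 3,
        max_percentile=float(100.0 * np.mean(smax < observed_max)),
        min_percentile=float(100.0 * np.mean(smin > observed_min)),
        z_max=float((observed_max - smax.mean()) / max(smax.std(), 1e-12)),
        z_min=float((smin.mean() - observed_min) / max(smin.std(), 1e-12)),
    )


def per_event_peaks(
    values,
    rate_hz: float,
    onset_frames,
    window: EventWindow = EventWindow(),
):
    """Maximum of the trace within each event's window (usable events only)."""
    values = np.asarray(values, dtype=float)
    pre_f, len_f = window.frames(rate_hz)
    onsets, _ = _usable_onsets(onset_frames, pre_f, len_f, values.size)
    if onsets.size == 0:
        raise InputError("no usable events")
    return _event_matrix(values, onsets, pre_f, len_f).max(axis=1), onsets


def activation_probability(
    values,
    rate_hz: float,
    onset_frames,
    window: EventWindow = EventWindow(),
    k: float = 5.0,
    baseline_frames=None,
    valid_periods=None,
    baseline_exclude_margin_s: float = 2.0,
):
    """Fraction of events whose peri-event peak exceeds ``k`` baseline SDs.

    An event is "coded" when its window peak exceeds the baseline mean plus
    ``k`` (default 5) standard deviations of the baseline trace; the
    activation probability is coded events / total events.  The baseline
    defaults to every frame outside all event windows (restricted to
    ``valid_periods`` when given).  Because a slow indicator's transients
    decay exponentially past the analysis window, an extra
    ``baseline_exclude_margin_s`` (default 2 s ≈ 4 decay constants) after
    each window is also excluded, so evoked tails do not inflate the
    baseline SD.
    """
    values = np.asarray(values, dtype=float)
    pre_f, len_f = window.frames(rate_hz)
    peaks, onsets = per_event_peaks(values, rate_hz, onset_frames, window)
    if baseline_frames is None:
        margin_f = max(0, frames_from_seconds(baseline_exclude_margin_s, rate_hz))
        base_mask = periods_to_mask(valid_periods, rate_hz, values.size)
        for f in onsets:
            base_mask[max(0, f - pre_f) : f - pre_f + len_f + margin_f] = False
        baseline_frames = np.flatnonzero(base_mask)
    baseline_frames = np.asarray(baseline_frames, dtype=int)
    if baseline_frames.size == 0:
        raise InputError("baseline is empty")
    base = values[baseline_frames]
    sd = base.std()
    if sd == 0:
        raise InputError("baseline SD is zero; activation probability undefined")
    coded = peaks > base.mean() + k * sd
    return float(coded.mean()), coded


def kinematic_correlation(
    peaks,
    kinematics: pd.DataFrame,
    n_permutations: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Pearson r between per-event response peaks and kinematic variables.

    P-values come from permuting the peak↔kinematics pairing
    ``n_permutations`` times (two-sided on |r|, add-one corrected).
    Zero-variance variables yield NaN and are flagged.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    peaks = np.asarray(peaks, dtype=float)
    rows = []
    for col in kinematics.columns:
        x = kinematics[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(peaks)
        if ok.sum() < 5:
            raise InputError(f"kinematic '{col}': need >= 5 events with defined values")
        xi, yi = x[ok], peaks[ok]
        if np.std(xi) == 0 or np.std(yi) == 0:
            rows.append({"variable": col, "r": np.nan, "p": np.nan, "defined": False,
                         "n": int(ok.sum())})
            continue
        r = float(np.corrcoef(xi, yi)[0, 1])
        xc = (xi - xi.mean()) / xi.std()
        yc = (yi - yi.mean()) / yi.std()
        perm = np.array([
            np.mean(xc * yc[rng.permutation(yc.size)]) for _ in range(n_permutations)
        ])
        p = (1.0 + np.sum(np.abs(perm) >= abs(r))) / (n_permutations + 1.0)
        rows.append({"variable": col, "r": r, "p": float(p), "defined": True,
                     "n": int(ok.sum())})
    return pd.DataFrame(rows)


def stop_kinematics(speed_trace, events: pd.DataFrame) -> pd.DataFrame:
    """Per-stop kinematics: pre-stop mean speed, peak deceleration, run duration.

    The pre-stop run is the contiguous forward segment preceding the onset;
    peak deceleration is the largest frame-to-frame speed drop (cm/s²) over
    the run and the transition frame.
    """
    from .behavior import STATE_FORWARD  # local import to avoid cycle at module load

    speed = np.asarray(speed_trace.speed, dtype=float)
    state = np.asarray(speed_trace.state)
    rate = speed_trace.rate_hz
    rows = []
    for rec in events.itertuples(index=False):
        onset = int(rec.onset_frame)
        j = onset - 1
        while j >= 0 and state[j] == STATE_FORWARD:
            j -= 1
        run = slice(j + 1, onset)
        if run.stop <= run.start:
            rows.append({"pre_stop_speed_cms": np.nan, "peak_decel_cms2": np.nan,
                         "run_duration_s": np.nan})
            continue
        seg = speed[run.start : min(onset + 1, speed.size)]
        decel = -np.diff(seg) * rate
        rows.append(
            {
                "pre_stop_speed_cms": float(speed[run].mean()),
                "peak_decel_cms2": float(decel.max()) if decel.size else np.nan,
                "run_duration_s": (run.stop - run.start) / rate,
            }
        )
    return pd.DataFrame(rows)
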