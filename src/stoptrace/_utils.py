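"""Small shared helpers: frame/second conversion, run-length segments."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


def frames_from_seconds(seconds: float, rate_hz: float) -> int:
    """Convert a duration threshold to whole frames, rounding half up.

    Detectors work at frame resolution (20 or 50 Hz video), so duration
    thresholds are expressed as a minimum frame count.
    """
    return int(math.floor(seconds * rate_hz + 0.5))


@dataclass(frozen=True)
class Segment:
    """A maximal run of identical state labels; ``stop`` is exclusive."""

    start: int
    stop: int
    label: str

    @property
    def length(self) -> int:
        return self.stop - self.start


def run_segments(labels: np.ndarray) -> list[Segment]:
    """Run-length encode a 1-D array of labels into maximal segments."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [labels.size]))
    return [Segment(int(s), int(e), str(labels[s])) for s, e in zip(starts, stops)]


def periods_to_mask(periods, rate_hz: float, n_frames: int) -> np.ndarray:
    """Boolean per-frame mask from ``[(start_s, end_s), ...]`` half-open periods.

    ``None`` means the whole recording is valid.
    """
    if periods is None:
        return np.ones(n_frames, dtype=bool)
    mask = np.zeros(n_frames, dtype=bool)
    t = np.arange(n_frames) / rate_hz
    for start, end in periods:
        if end <= start:
            raise ValueError(f"invalid period ({start}, {end}): end must exceed start")
        mask |= (t >= start) & (t < end)
    return mask


def nearest_frame(time_s, rate_hz: float):
    """Nearest frame index on a clock of the given rate (shared start trigger)."""
    return np.rint(np.asarray(time_s) * rate_hz).astype(int)
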