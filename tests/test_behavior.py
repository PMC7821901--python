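"""Oriented speed, state classification, and rule-based event detection."""

import numpy as np
import pandas as pd
import pytest

from stoptrace import (
    InputError,
    LandmarkTrack,
    SpeedTrace,
    classify_state,
    detect_long_stops,
    detect_starts,
    detect_stops,
    oriented_speed,
    read_annotations,
)
from stoptrace.behavior import STATE_FORWARD, STATE_STATIONARY


def _track_from_centroid(centroid, heading, rate=20.0):
    """Build a landmark track with ears 1 cm apart and spine 2 cm behind."""
    n = centroid.shape[0]
    normal = np.column_stack([-heading[:, 1], heading[:, 0]])
    return LandmarkTrack(
        time=np.arange(n) / rate,
        left_ear=centroid + 0.5 * normal,
        right_ear=centroid - 0.5 * normal,
        spine=centroid - 2.0 * heading,
        rate_hz=rate,
    )


def _speed_trace(speed, rate=20.0):
    speed = np.asarray(speed, dtype=float)
    return SpeedTrace(
        time=np.arange(speed.size) / rate,
        speed=speed,
        state=classify_state(speed),
        rate_hz=rate,
    )


class TestOrientedSpeed:
    def test_constant_coordinates_give_zero_stationary(self):
        n = 50
        centroid = np.tile([3.0, 4.0], (n, 1))
        heading = np.tile([1.0, 0.0], (n, 1))
        trace = oriented_speed(_track_from_centroid(centroid, heading))
        assert np.allclose(trace.speed, 0.0)
        assert np.all(trace.state == STATE_STATIONARY)

    def test_translation_along_body_axis_recovers_speed(self):
        rate, v = 20.0, 4.0
        t = np.arange(100) / rate
        centroid = np.column_stack([v * t, np.zeros_like(t)])
        heading = np.tile([1.0, 0.0], (100, 1))
        trace = oriented_speed(_track_from_centroid(centroid, heading))
        assert np.allclose(trace.speed[1:], v, atol=1e-9)
        assert np.all(trace.state[1:] == STATE_FORWARD)

    def test_circular_walk_matches_tangential_speed(self):
        # heading tangent to a circle; oracle: numeric differentiation of the path
        rate, v, radius = 50.0, 6.0, 20.0
        t = np.arange(400) / rate
        theta = v * t / radius
        centroid = radius * np.column_stack([np.cos(theta), np.sin(theta)])
        heading = np.column_stack([-np.sin(theta), np.cos(theta)])
        trace = oriented_speed(_track_from_centroid(centroid, heading, rate))
        assert np.allclose(trace.speed[1:], v, rtol=0.02)

    def test_degenerate_orientation_carries_previous_heading(self):
        n, rate = 20, 20.0
        t = np.arange(n) / rate
        centroid = np.column_stack([4.0 * t, np.zeros(n)])
        heading = np.tile([1.0, 0.0], (n, 1))
        track = _track_from_centroid(centroid, heading, rate)
        track.spine[10] = 0.5 * (track.left_ear[10] + track.right_ear[10])  # collapse
        trace = oriented_speed(track)
        assert trace.speed[10] == pytest.approx(4.0, abs=1e-9)

    def test_single_frame_rejected(self):
        track = _track_from_centroid(np.zeros((1, 2)), np.array([[1.0, 0.0]]))
        with pytest.raises(InputError):
            oriented_speed(track)


@pytest.mark.parametrize(
    "speed,expected",
    [(5.0, "forward"), (0.0, "stationary"), (-5.0, "backward"),
     (3.0, "stationary"), (-3.0, "stationary")],
)
def test_classify_state_thresholds(speed, expected):
    assert classify_state([speed])[0] == expected


def _run_then_stop(run_s, stop_s, run_speed, rate=20.0, tail_stop=True):
    f = int(round(run_s * rate))
    s = int(round(stop_s * rate))
    return _speed_trace([run_speed] * f + [0.0] * s, rate)


class TestDetectStops:
    def test_qualifying_run_and_immobility_yield_one_stop(self):
        trace = _run_then_stop(1.0, 1.0, 10.0)
        events = detect_stops(trace)
        assert len(events) == 1
        assert events.onset_frame.iloc[0] == 20

    def test_short_run_rejected(self):
        trace = _run_then_stop(0.2, 1.0, 10.0)
        assert len(detect_stops(trace)) == 0

    def test_slow_run_rejected(self):
        trace = _run_then_stop(1.0, 1.0, 4.0)
        assert len(detect_stops(trace)) == 0

    def test_empty_trace_gives_empty_list(self):
        trace = _speed_trace([])
        assert len(detect_stops(trace)) == 0

    def test_stationary_padding_at_end_is_invariant(self):
        # same stops at the same onsets (the recorded immobility offset may
        # legitimately extend with the padding)
        trace = _run_then_stop(1.0, 1.0, 10.0)
        padded = _speed_trace(list(trace.speed) + [0.0] * 40)
        before = detect_stops(trace)[["type", "onset_frame", "onset_s"]]
        after = detect_stops(padded)[["type", "onset_frame", "onset_s"]]
        pd.testing.assert_frame_equal(before, after)

    def test_raising_speed_threshold_never_adds_stops(self):
        rng = np.random.default_rng(0)
        speed = np.clip(rng.normal(5, 4, 2000), -2, None)
        trace = _speed_trace(speed)
        counts = [
            len(detect_stops(trace, min_avg_run_speed=th)) for th in (0, 2, 4, 6, 8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_valid_periods_restrict_onsets(self):
        speed = ([10.0] * 20 + [0.0] * 20) * 3
        trace = _speed_trace(speed)
        all_events = detect_stops(trace)
        assert len(all_events) == 3
        restricted = detect_stops(trace, valid_periods=[(2.0, 4.0)])
        assert len(restricted) < 3
        for t in restricted.onset_s:
            assert 2.0 <= t < 4.0


class TestDetectLongStops:
    def test_immobility_below_three_seconds_rejected(self):
        trace = _run_then_stop(1.0, 2.9, 10.0)
        assert len(detect_long_stops(trace)) == 0

    def test_short_run_long_immobility_accepted(self):
        trace = _run_then_stop(0.15, 3.5, 10.0)
        events = detect_long_stops(trace)
        assert len(events) == 1

    def test_long_stops_nest_within_stops(self):
        # when the preceding run also satisfies the stop criteria, every
        # long stop is also a stop
        trace = _run_then_stop(1.0, 3.5, 10.0)
        stops = set(detect_stops(trace).onset_frame)
        longs = set(detect_long_stops(trace).onset_frame)
        assert longs <= stops


class TestDetectStarts:
    def test_quiescence_then_locomotion_yields_one_start(self):
        trace = _speed_trace([0.0] * 20 + [10.0] * 20)
        events = detect_starts(trace)
        assert len(events) == 1
        assert events.onset_frame.iloc[0] == 20

    def test_restless_quiescence_rejected(self):
        trace = _speed_trace([2.5] * 20 + [10.0] * 20)
        assert len(detect_starts(trace)) == 0

    def test_all_stationary_has_no_starts(self):
        trace = _speed_trace([0.0] * 100)
        assert len(detect_starts(trace)) == 0


class TestReadAnnotations:
    def test_grooming_epochs_round_trip(self, tmp_path):
        path = tmp_path / "ann.csv"
        pd.DataFrame(
            {"type": ["grooming"] * 3, "onset_s": [1.0, 5.0, 9.0],
             "offset_s": [2.0, 7.0, 10.0]}
        ).to_csv(path, index=False)
        events = read_annotations(path, duration_s=20.0, rate_hz=20.0)
        assert len(events) == 3
        assert set(events.provenance) == {"annotated"}

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        assert len(read_annotations(path)) == 0

    def test_onset_beyond_recording_rejected_with_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"type": ["stop"], "onset_s": [99.0]}).to_csv(path, index=False)
        with pytest.raises(InputError, match="row 0"):
            read_annotations(path, duration_s=10.0)

    def test_unknown_type_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"type": ["sprint"], "onset_s": [1.0]}).to_csv(path, index=False)
        with pytest.raises(InputError, match="row 0"):
            read_annotations(path)
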