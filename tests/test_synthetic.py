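"""Behavior/calcium generator: schedules, planted responses, forward model."""

import math

import numpy as np
import pytest
from scipy import stats

from stoptrace import (
    InputError,
    SimulationConfig,
    calcium_kernel,
    detect_stops,
    events_to_calcium,
    oriented_speed,
    rate_to_calcium,
    simulate_behavior,
    simulate_cell_rate,
    simulate_dataset,
)
from stoptrace.synthetic import DurationSpec, GroundTruthCell, make_cohort

from conftest import make_cell


def fixed(d):
    return DurationSpec(d, d, d)


class TestSimulateBehavior:
    def test_zero_bout_probability_gives_all_stationary(self):
        cfg = SimulationConfig(duration_s=60.0, bout_prob=0.0, grooming_prob=0.0, seed=0)
        schedule, speed, _ = simulate_behavior(cfg)
        assert set(schedule.intervals.state) == {"stationary"}
        assert len(schedule.event_table("stop")) == 0
        assert np.allclose(speed.speed, 0.0)

    def test_planted_bout_count_round_trips_through_detector(self):
        # 12 bouts of 2 s at 10 cm/s separated by 2 s immobility
        cfg = SimulationConfig(
            duration_s=12 * 4 + 2.0,
            bout_duration_s=fixed(2.0),
            immobility_duration_s=fixed(2.0),
            run_speed_cms=10.0,
            grooming_prob=0.0,
            seed=3,
        )
        schedule, speed, track = simulate_behavior(cfg)
        gt = schedule.event_table("stop")
        assert len(gt) == 12
        detected = detect_stops(oriented_speed(track))
        assert len(detected) == 12
        assert np.all(np.abs(detected.onset_frame.values - gt.onset_frame.values) <= 1)

    def test_identical_seed_gives_identical_outputs(self):
        cfg = SimulationConfig(duration_s=90.0, seed=11)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert a.schedule.intervals.equals(b.schedule.intervals)
        assert np.array_equal(a.speed.speed, b.speed.speed)
        assert a.traces.equals(b.traces)

    def test_too_short_duration_fails(self):
        with pytest.raises(InputError):
            simulate_behavior(SimulationConfig(duration_s=0.6, seed=0))

    def test_landmarks_reproduce_speed_through_oriented_speed(self, session_behavior):
        _, speed, track = session_behavior
        recomputed = oriented_speed(track)
        assert np.allclose(recomputed.speed, speed.speed, atol=1e-9)

    def test_intervals_tile_duration_without_overlap(self, session_behavior):
        schedule, _, _ = session_behavior
        iv = schedule.intervals
        assert iv.start_s.iloc[0] == 0.0
        assert iv.end_s.iloc[-1] == pytest.approx(schedule.duration_s)
        assert np.allclose(iv.end_s.values[:-1], iv.start_s.values[1:])

    def test_grooming_only_inside_immobility(self):
        cfg = SimulationConfig(duration_s=200.0, grooming_prob=1.0, seed=5)
        schedule, speed, _ = simulate_behavior(cfg)
        groom = schedule.event_table("grooming")
        assert len(groom) > 0
        for rec in groom.itertuples(index=False):
            sel = (speed.time >= rec.onset_s) & (speed.time <= rec.offset_s)
            assert np.all(np.abs(speed.speed[sel]) <= 3.0)


class TestSimulateCellRate:
    def test_uncorrelated_zero_amp_is_flat_baseline(self, session_behavior, session_config):
        schedule, _, _ = session_behavior
        cell = make_cell("uncorrelated", response_amp=0.0)
        rate = simulate_cell_rate(schedule, cell, session_config, np.random.default_rng(0))
        assert np.allclose(rate, cell.resolved_baseline_rate)

    def test_reliability_recovered_within_binomial_interval(
        self, session_behavior, session_config
    ):
        schedule, _, _ = session_behavior
        p_true = 0.6
        n_resp = n_events = 0
        base = make_cell("stop_excited", reliability_p=p_true, response_amp=1.0).resolved_baseline_rate
        for seed in range(4):
            cell = make_cell("stop_excited", reliability_p=p_true, response_amp=1.0)
            rate = simulate_cell_rate(schedule, cell, session_config,
                                      np.random.default_rng(seed))
            cal = session_config.calcium_rate_hz
            for t0 in schedule.onsets("stop"):
                f = int(round(t0 * cal))
                n_events += 1
                n_resp += rate[f] > base + 1e-9
        lo, hi = stats.binom.interval(0.95, n_events, p_true)
        assert lo <= n_resp <= hi

    def test_inhibited_cell_suppressed_after_stops(self, session_behavior, session_config):
        schedule, _, _ = session_behavior
        cell = make_cell("stop_inhibited", reliability_p=1.0)
        rate = simulate_cell_rate(schedule, cell, session_config, np.random.default_rng(1))
        cal = session_config.calcium_rate_hz
        post = max(1, int(round(1.25 * cal)))
        for t0 in schedule.onsets("stop"):
            f = int(round(t0 * cal))
            assert rate[f : f + post].mean() < cell.resolved_baseline_rate

    def test_sustained_response_spans_the_state(self, session_behavior, session_config):
        schedule, _, _ = session_behavior
        cell = make_cell("stop_excited", reliability_p=1.0, sustained=True)
        rate = simulate_cell_rate(schedule, cell, session_config, np.random.default_rng(2))
        cal = session_config.calcium_rate_hz
        stops = schedule.event_table("stop")
        mid = ((stops.onset_s + stops.offset_s) / 2 * cal).round().astype(int)
        assert np.all(rate[mid] > cell.resolved_baseline_rate)


class TestRateToCalcium:
    def test_zero_rate_zero_noise_gives_zero_trace(self):
        cfg = SimulationConfig(noise_sd=0.0, seed=0)
        out = rate_to_calcium(np.zeros(200), cfg)
        assert np.allclose(out, 0.0)

    def test_single_event_matches_closed_form_kernel(self):
        cfg = SimulationConfig(seed=0)
        amps = np.zeros(400)
        amps[50] = 1.0
        out = events_to_calcium(amps, cfg)
        tr, td = cfg.kernel_rise_s, cfg.kernel_decay_s
        t_pk = math.log(td / tr) / (1 / tr - 1 / td)
        peak = math.exp(-t_pk / td) - math.exp(-t_pk / tr)
        t = np.arange(350) / cfg.calcium_rate_hz
        expected = (np.exp(-t / td) - np.exp(-t / tr)) / peak
        assert np.allclose(out[50:], expected[: 350], atol=1e-9)

    def test_convolution_is_linear_in_amplitudes(self):
        cfg = SimulationConfig(seed=0)
        rng = np.random.default_rng(3)
        amps = rng.uniform(0, 2, 300)
        assert np.allclose(
            events_to_calcium(2 * amps, cfg), 2 * events_to_calcium(amps, cfg), atol=1e-12
        )

    def test_negative_rate_rejected(self):
        with pytest.raises(InputError):
            rate_to_calcium(np.array([0.1, -0.1]), SimulationConfig(seed=0))

    def test_kernel_unit_peak_and_support(self):
        k = calcium_kernel()
        assert 0.99 <= k.max() <= 1.0
        assert abs(k[-1]) < 1e-10


class TestCohort:
    def test_fractions_sum_to_cell_count(self):
        cells = make_cohort(n_cells=21)
        assert len(cells) == 21
        classes = [c.cell_class for c in cells]
        assert classes.count("stop_excited") in (10, 11)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(InputError):
            make_cohort(fractions={"stop_excited": 0.6})

    def test_invalid_cell_class_rejected(self):
        with pytest.raises(InputError):
            GroundTruthCell("c", "sprint_excited")


def test_round_trip_detection_over_seeds():
    """Stop/long-stop/start onsets recovered exactly on clean traces."""
    from stoptrace import detect_long_stops, detect_starts

    for seed in range(5):
        cfg = SimulationConfig(duration_s=150.0, seed=seed)
        schedule, _, track = simulate_behavior(cfg)
        trace = oriented_speed(track)
        for etype, det in [
            ("stop", detect_stops),
            ("long_stop", detect_long_stops),
            ("start", detect_starts),
        ]:
            got = det(trace).onset_frame.values
            want = schedule.event_table(etype).onset_frame.values
            assert np.array_equal(got, want), (seed, etype)
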