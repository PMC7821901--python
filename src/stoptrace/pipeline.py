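"""End-to-end orchestration: simulate → detect → process → test → classify → decode.

``run_pipeline`` executes the full analysis on either a simulated session or
a directory of input CSVs, and writes a reproducible bundle: per-cell result
CSV, composition/pairing JSON, decoding JSON, event CSVs, and a run log with
every resolved parameter.  Outputs are byte-deterministic for a fixed
config and seed.
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from ._utils import nearest_frame, periods_to_mask
from .behavior import (
    EVENT_GROOMING,
    EVENT_START,
    EVENT_STOP,
    detect_long_stops,
    detect_starts,
    detect_stops,
    oriented_speed,
    read_annotations,
)
from .classify import classify_cell, composition_test, start_stop_pairing
from .decoding import build_population_matrix, jackknife_train_eval, unpredicted_stops
from .errors import DegenerateAnalysisError, InputError
from .events import (
    EventWindow,
    activation_probability,
    event_triggered_average,
    resampling_test,
)
from .signal import gaussian_smooth, deconvolve, dff_normalize
from .synthetic import (
    DurationSpec,
    SimulationConfig,
    make_cohort,
    simulate_dataset,
)


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters, defaulting to the protocol's printed values."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cohort_n_cells: int = 20
    cohort_fractions: dict | None = None  # default 50/25/25 stop-excited/-inhibited/uncorr
    cohort_reliability_p: float = 0.6
    cohort_response_amp: float = 0.5
    cohort_sustained: bool = False
    context: str = "open_field"

    # event analysis
    window_pre_s: float = 0.25
    window_length_s: float = 1.5
    grooming_window_length_s: float = 4.25
    n_shuffles: int = 1000
    alpha: float = 0.05
    activation_k_sd: float = 5.0
    normalize_traces: bool = False   # simulated traces are already ΔF/F
    smooth_half_width_s: float = 0.15
    deconvolve_tau_s: float = 0.5

    # decoding
    decoder_C: float = 1.0
    decoder_splits: int = 5
    decoder_train_frac: float = 0.8

    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_dict(io.read_config_file(path))


@dataclass
class RunReport:
    outdir: Path
    cell_results: pd.DataFrame
    composition: dict
    decoding: dict
    events: pd.DataFrame


def _analyze_cell(
    values_smoothed: np.ndarray,
    rate: float,
    onsets_cal: np.ndarray,
    window: EventWindow,
    valid_periods,
    config: RunConfig,
    rng: np.random.Generator,
) -> dict:
    eta = event_triggered_average(values_smoothed, rate, onsets_cal, window)
    res = resampling_test(
        values_smoothed,
        rate,
        onsets_cal,
        window,
        valid_periods=valid_periods,
        n_shuffles=config.n_shuffles,
        alpha=config.alpha,
        rng=rng,
    )
    return {
        "n_events": eta.n_events,
        "peak": eta.peak,
        "trough": eta.trough,
        "dT_peak_s": eta.time_to_peak_s,
        "excited": res.excited,
        "inhibited": res.inhibited,
        "max_percentile": res.max_percentile,
        "min_percentile": res.min_percentile,
        "low_n": res.low_n,
        "cell_class": classify_cell(res),
    }


def run_pipeline(config: RunConfig, outdir, valid_periods=None) -> RunReport:
    """Run the full analysis and write the report bundle into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fractions = config.cohort_fractions or {
        "stop_excited": 0.5,
        "stop_inhibited": 0.25,
        "uncorrelated": 0.25,
    }
    cells = make_cohort(
        n_cells=config.cohort_n_cells,
        fractions=fractions,
        reliability_p=config.cohort_reliability_p,
        response_amp=config.cohort_response_amp,
        sustained=config.cohort_sustained,
        seed=config.simulation.seed,
    )
    ds = simulate_dataset(config.simulation, cells)
    cal_rate = config.simulation.calcium_rate_hz

    # --- behavior: recompute oriented speed from landmarks, detect events ---
    speed = oriented_speed(ds.landmarks)
    stops = detect_stops(speed, valid_periods=valid_periods)
    long_stops = detect_long_stops(speed, valid_periods=valid_periods)
    starts = detect_starts(speed, valid_periods=valid_periods)
    # grooming is manually annotated; the simulator writes the annotation file
    groom_path = outdir / "grooming_annotations.csv"
    io.write_events(ds.schedule.event_table(EVENT_GROOMING).assign(provenance="annotated"),
                    groom_path)
    grooming = read_annotations(groom_path, duration_s=config.simulation.duration_s,
                                rate_hz=ds.schedule.rate_hz)
    events = pd.concat([stops, long_stops, starts, grooming], ignore_index=True)

    # --- signal processing ---
    raw = ds.traces
    if config.normalize_traces:
        raw = raw.apply(lambda c: pd.Series(dff_normalize(c.to_numpy()), index=c.index))
    smoothed = raw.apply(
        lambda c: pd.Series(
            gaussian_smooth(c.to_numpy(), cal_rate, config.smooth_half_width_s),
            index=c.index,
        )
    )
    deconv = raw.apply(
        lambda c: pd.Series(
            deconvolve(c.to_numpy(), cal_rate, config.deconvolve_tau_s), index=c.index
        )
    )

    window = EventWindow(config.window_pre_s, config.window_length_s)
    groom_window = EventWindow(config.window_pre_s, config.grooming_window_length_s)

    behaviors = {
        EVENT_STOP: stops,
        EVENT_START: starts,
        EVENT_GROOMING: grooming,
    }
    ss = np.random.SeedSequence(config.seed)
    cell_rngs = [np.random.default_rng(c) for c in ss.spawn(len(ds.cell_ids) + 1)]

    meta = ds.metadata.set_index("cell_id")
    rows = []
    for i, cid in enumerate(ds.cell_ids):
        vals = smoothed[cid].to_numpy()
        rng = cell_rngs[i]
        for beh, ev in behaviors.items():
            if ev.empty:
                continue
            onsets_cal = nearest_frame(ev["onset_s"].to_numpy(), cal_rate)
            try:
                rec = _analyze_cell(vals, cal_rate, onsets_cal, window,
                                    valid_periods, config, rng)
            except InputError:
                continue
            rec.update(
                cell_id=cid,
                behavior=beh,
                context=config.context,
                location=meta.loc[cid, "location"],
                true_class=meta.loc[cid, "cell_class"],
            )
            if beh == EVENT_STOP:
                prob, _ = activation_probability(
                    vals, cal_rate, onsets_cal, window,
                    k=config.activation_k_sd, valid_periods=valid_periods,
                )
                rec["activation_prob"] = prob
            if beh == EVENT_GROOMING:
                sus = event_triggered_average(vals, cal_rate, onsets_cal, groom_window)
                rec["grooming_sustained_peak"] = sus.peak
            rows.append(rec)
    cell_results = pd.DataFrame(rows)
    front = ["cell_id", "behavior", "context", "location", "cell_class", "true_class",
             "n_events", "peak", "trough", "dT_peak_s", "excited", "inhibited",
             "activation_prob"]
    cell_results = cell_results.reindex(
        columns=front + [c for c in cell_results.columns if c not in front]
    )

    # --- composition tests per behavior ---
    composition: dict = {}
    for beh in behaviors:
        sub = cell_results[cell_results["behavior"] == beh]
        entry: dict = {"n_cells": int(len(sub))}
        try:
            table, p = composition_test(sub)
            entry["table"] = {str(g): {str(c): int(v) for c, v in row.items()}
                              for g, row in table.iterrows()}
            entry["p"] = p
        except InputError as exc:
            entry["p"] = None
            entry["skipped"] = str(exc)
        composition[beh] = entry
    stop_res = cell_results[cell_results["behavior"] == EVENT_STOP]
    start_res = cell_results[cell_results["behavior"] == EVENT_START]
    if not stop_res.empty and not start_res.empty:
        pairing = start_stop_pairing(stop_res, start_res)
        composition["start_stop_pairing"] = pairing.counts

    # --- decoding ---
    states_cal = ds.speed.state[
        np.clip(
            nearest_frame(ds.trace_time, ds.speed.rate_hz), 0, ds.speed.n_frames - 1
        )
    ]
    mask = periods_to_mask(valid_periods, cal_rate, len(ds.trace_time))
    pm = build_population_matrix(smoothed, states_cal, cal_rate, valid_mask=mask)
    decoding: dict = {}
    try:
        report = jackknife_train_eval(
            pm,
            n_splits=config.decoder_splits,
            train_frac=config.decoder_train_frac,
            C=config.decoder_C,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        decoding = report.to_dict()
        pred_full = report.predicted_full(len(ds.trace_time))
        stop_onsets_cal = nearest_frame(stops["onset_s"].to_numpy(), cal_rate)
        flags = unpredicted_stops(pred_full, stop_onsets_cal, cal_rate,
                                  window_s=config.window_length_s)
        decoding["n_stops"] = int(flags.size)
        decoding["n_unpredicted_stops"] = int(flags.sum())
        pd.DataFrame(
            {"frame": np.arange(len(ds.trace_time)), "time_s": ds.trace_time,
             "predicted_walking": pred_full}
        ).to_csv(outdir / "predicted_state.csv", index=False)
    except DegenerateAnalysisError as exc:
        decoding = {"skipped": str(exc)}

    # --- write the bundle ---
    io.write_landmarks(ds.landmarks, outdir / "landmarks.csv")
    io.write_speed(speed, outdir / "speed.csv")
    io.write_events(events, outdir / "events.csv")
    io.write_events(ds.schedule.events, outdir / "ground_truth_events.csv")
    io.write_traces(ds.traces, ds.trace_time, outdir / "traces_raw.csv", "raw")
    io.write_traces(smoothed, ds.trace_time, outdir / "traces_smoothed.csv", "smoothed")
    io.write_traces(deconv, ds.trace_time, outdir / "traces_deconvolved.csv", "deconvolved")
    io.write_cell_metadata(ds.metadata, outdir / "cells.csv")
    cell_results.to_csv(outdir / "cell_results.csv", index=False)
    io.write_json(composition, outdir / "composition.json")
    io.write_json(decoding, outdir / "decoding.json")
    io.write_json(config.to_dict(), outdir / "config.json")
    io.write_json(
        {
            "package": "stoptrace",
            "version": __version__,
            "python": sys.version.split()[0],
            "seed": config.seed,
            "parameters": config.to_dict(),
            "n_cells": len(ds.cell_ids),
            "n_events": {k: int(len(v)) for k, v in behaviors.items()},
            "valid_periods": valid_periods,
        },
        outdir / "run_log.json",
    )
    return RunReport(
        outdir=outdir,
        cell_results=cell_results,
        composition=composition,
        decoding=decoding,
        events=events,
    )


def make_fixtures(outdir, scale: str = "tiny") -> RunConfig:
    """Write a deterministic synthetic dataset bundle for tests and demos.

    ``tiny`` runs the whole pipeline in seconds: 40 s of behavior, six cells,
    immobility long enough that stop, long-stop, start and grooming events
    are all present.  ``default`` is the standard 600 s cohort.
    """
    if scale == "tiny":
        sim = SimulationConfig(
            duration_s=40.0,
            bout_duration_s=DurationSpec(2.0, 1.5, 3.0),
            immobility_duration_s=DurationSpec(3.2, 3.0, 4.0),
            grooming_prob=1.0,
            seed=7,
        )
        config = RunConfig(
            simulation=sim,
            cohort_n_cells=6,
            n_shuffles=200,
            seed=7,
        )
    elif scale == "default":
        config = RunConfig()
    else:
        raise InputError(f"unknown fixture scale '{scale}'")
    run_pipeline(config, outdir)
    return config
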