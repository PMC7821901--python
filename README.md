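# stoptrace

Analysis of single-cell calcium imaging recordings from freely moving mice,
centered on the question of how brainstem neurons encode transitions between
locomotion and immobility.  The package detects behavioral events (locomotor
**stops**, **long stops**, **starts**, and manually annotated **grooming**)
from pose-tracking landmarks, processes micro-endoscopic ΔF/F traces, tests
each cell's peri-event modulation against a shuffle null, quantifies
event-wise activation probability, compares cell-class composition between
groups with an exact r×c test, and decodes the locomotor state from
population activity with a jack-knifed linear SVM.  A synthetic-data
generator with planted ground truth backs every stage with
parameter-recovery tests.

Intended users: systems-neuroscience labs analyzing miniscope (one-photon
micro-endoscope) recordings aligned to episodic locomotor behavior, and
anyone who needs a tested reference implementation of the shuffle-based
peri-event significance test or the Freeman–Halton exact test.

## The method

**Behavior.** The oriented speed is the frame-to-frame displacement of the
head (ear midpoint) projected on the body axis (spine → ear midpoint),
divided by the frame interval.  Frames are labeled forward (> 3 cm/s),
backward (< −3 cm/s) or stationary.  A **stop** is an immobility onset
lasting ≥ 200 ms after a forward run of ≥ 250 ms with mean speed > 5 cm/s
(long stops: ≥ 3 s immobility after ≥ 100 ms of running, no mean-speed
condition); a **start** is a forward onset of ≥ 200 ms after ≥ 250 ms of
quiescence with mean |speed| < 2 cm/s.

**Signal.** ΔF/F = F / mean(F) − 1; smoothing by a unit-area Gaussian with
150 ms half-width (σ = 0.150/√(2 ln 2) s); first-order deconvolution
S_d = τ·dS/dt + S with τ = 0.5 s (GCaMP6s decay), which returns a
firing-rate estimate still blurred by the 50–100 ms indicator rise time.

**Statistics.** For each cell, the max and min of the event-triggered
average in a 1.5 s window starting 0.25 s before the event are compared
with 1000 shuffles in which the same number of pseudo-event times is drawn
uniformly within the analyzed periods: a cell is *excited* when its
observed max strictly exceeds the 95th percentile of shuffled maxima,
*inhibited* when its min falls below the 5th percentile of shuffled minima,
otherwise *uncorrelated*.  The stop-activation probability is the fraction
of events whose peri-event peak exceeds 5 SDs of the baseline ΔF/F.
Group composition (e.g. medial vs lateral implant × three classes) is
tested with the Freeman–Halton exact P for r×c tables (exhaustive
multivariate-hypergeometric enumeration).  Decoding uses a linear
maximum-margin classifier (hinge loss, L2, class-balanced) on frame-wise
population vectors, validated by five random contiguous 80/20 train/test
splits with ROC/AUC on held-out chunks.

## Worked example

```sh
stoptrace run --seed 4 --out bundle/
```

simulates the default cohort (600 s at 20 Hz, 20 cells planted as 50%
stop-excited / 25% stop-inhibited / 25% uncorrelated), detects events from
the emitted landmark track, and analyzes every cell.  It prints:

```
stop-class fractions: {'excited': 0.5, 'inhibited': 0.3, 'uncorrelated': 0.2}
decoding: {'n_splits': 5, 'split_aucs': [0.809, 0.872, 0.939, 0.875, 0.871],
           'mean_auc': 0.873, 'resampled_splits': 0,
           'n_stops': 119, 'n_unpredicted_stops': 0}
bundle written to bundle/
```

The stop-class fractions are the shuffle-test classification of the 20
cells at the 119 detected stops — within one cell of the planted 10/5/5
composition.  The mean AUC of 0.87 says the population activity separates
walking from stationary frames well above chance on held-out data.  The
bundle directory contains the landmark/speed/event CSVs, raw/smoothed/
deconvolved traces, per-cell results (`cell_results.csv`), composition and
decoding JSON reports, and a run log with every resolved parameter.
Library use mirrors the CLI:

```python
from stoptrace import RunConfig, run_pipeline
report = run_pipeline(RunConfig(), "bundle/")
print(report.cell_results.head())
```

The signal stages also compose as scikit-learn transformers
(`DeltaFOverF`, `GaussianSmoother`, `FirstOrderDeconvolver`), and the
decoder is a scikit-learn estimator (`StopDecoder`).

## File schemas

All times in seconds, frames 0-based, positions cm, speeds cm/s.

| file | columns |
| --- | --- |
| landmarks.csv | `frame, time_s, {left_ear,right_ear,spine}_{x,y}` |
| speed.csv | `frame, time_s, speed_cms, state` |
| events.csv | `type, onset_frame, onset_s, offset_frame, offset_s, provenance` |
| traces_*.csv | `time_s` + one ΔF/F column per cell id (variant in sidecar `.meta.json`) |
| cells.csv | `cell_id, cell_class, reliability_p, response_amp, sustained, location` |
| cell_results.csv | `cell_id, behavior, context, location, cell_class, n_events, peak, trough, dT_peak_s, excited, inhibited, activation_prob, …` |

CLI exit codes: 0 success, 2 input error, 3 degenerate analysis.
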