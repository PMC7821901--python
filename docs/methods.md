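# Methods

This note documents the models, estimators and numerical choices behind
`stoptrace`, and what the synthetic ground truth does and does not
establish about real recordings.

## Behavioral model and event definitions

The oriented speed at frame *i* is the backward difference of the ear
midpoint position projected on the unit body-axis vector (spine → ear
midpoint) at frame *i*, divided by the frame interval; the first frame
copies the second.  The ear midpoint stands in for the body centroid (the
tracked points are the two ears and one spine landmark; the projection, not
the choice of reference point, carries the signal).  Frames whose body axis
is degenerate (ears coinciding with the spine point, e.g. a tracking
failure) reuse the previous valid orientation rather than producing NaNs.

States: forward > 3 cm/s, backward < −3 cm/s, stationary otherwise
(thresholds configurable; camera geometry can shift the effective value by
a few percent).  Event detectors operate on maximal same-state segments at
frame resolution; duration thresholds convert to whole frames by
round-half-up, so "200 ms at 20 Hz" means 4 frames and "250 ms at 50 Hz"
means 13.  Sub-frame threshold excursions therefore cannot reset an
immobility period — excursions are only visible at frame resolution.

Defaults (seconds, cm/s):

| event | state before | state after | conditions |
| --- | --- | --- | --- |
| stop | forward ≥ 0.25 | stationary ≥ 0.2 | mean run speed > 5 |
| long stop | forward ≥ 0.1 | stationary ≥ 3 | no mean-speed condition |
| start | stationary ≥ 0.25 | forward ≥ 0.2 | mean \|speed\| before < 2 |

Onset = first frame of the new state.  Detection can be restricted to
`valid_periods` (e.g. treadmill-engaged epochs); grooming is read from
manual annotation files, never detected.  Segment durations are judged on
observed frames only, including a trailing segment cut off by the end of
the recording; recordings produced by the simulator always end at rest, so
appending stationary padding never changes the detected events.  The
oriented speed is not smoothed before thresholding by default (a boxcar
window is exposed as config).

## Synthetic data generator

`synthetic.simulate_behavior` tiles the session with alternating locomotion
bouts and immobility periods drawn from truncated shifted-exponential
distributions (bouts: mean 4 s in [1, 15]; immobility: mean 1.5 s in
[0.5, 8]), always ending at rest.  Speed follows a trapezoid per bout:
cruising at 12 cm/s with 100 ms linear ramps, so deceleration before each
stop is a defined kinematic quantity.  Head position is the exact time
integral of that profile (computed on a 20× finer grid), and the landmark
geometry (ears 1 cm apart, spine 2 cm behind the ear midpoint along the
heading, straight-line path) reproduces the speed profile exactly through
the oriented-speed computation — ground-truth onsets are read off the
emitted trace itself, which is what makes the detection round trip exact
rather than approximate.  With probability 0.15 an immobility period of at
least 1 s contains grooming in its middle half; grooming is mutually
exclusive with locomotion by construction.

Cells are planted as one of five classes.  Excited classes respond to each
preferred event (stop, start, or grooming onset) with probability
`reliability_p` (default 0.6) by a rate bump whose time integral is
`response_amp` ΔF/F units (default 0.5), spread over 200 ms, or extended
through the whole behavioral state for `sustained` cells.  The
stop-inhibited class carries a tonic rate (1.5 a.u./s) suppressed to zero
for 1.25 s (or through the state) at responsive stops.  Uncorrelated cells
receive event-independent bumps at 0.1 /s.  Rates convert to fluorescence
by drawing Poisson events of quantal size 0.05 ΔF/F, convolving with the
unit-peak difference-of-exponentials kernel

    k(t) = exp(−t/τ_d) − exp(−t/τ_r),  τ_r = 75 ms, τ_d = 0.5 s,

(normalized by its analytic continuous peak; truncated where the decay term
falls below 1e−12 of the peak) and adding white Gaussian noise of SD 0.1.
The scale choices — quantal size, amplitudes, baseline rates, noise — are
plausible for a slow indicator in one-photon imaging but are free
parameters, not calibrated values; real transient amplitudes for these
cells are not established.

What the generator does **not** emulate: out-of-focus background and
neuropil contamination, motion artifacts, demixing-induced trace scaling,
bursty or history-dependent firing, arena geometry and turning, backward
treadmill translation during stops, and speed-tracking noise.  Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated forward model, not robustness to those nuisances.

## Trace processing

ΔF/F is F divided by its time-averaged mean minus one (undefined, and
rejected, for non-positive mean).  Smoothing convolves with a truncated
(±4σ) unit-area Gaussian whose half-width at half-maximum is 150 ms
(σ = 0.150/√(2 ln 2) ≈ 0.127 s) — "half-width" is read as HWHM, the most
common convention, and both the width and the reading are configurable.
Edges renormalize the kernel over the in-bounds support, so constants are
exactly preserved everywhere.  Deconvolution applies S_d = τ dS/dt + S
with central differences in the interior and one-sided differences at the
edges, keeping the estimate lag-symmetric; the result approximates the
firing rate filtered by the indicator's 50–100 ms rise (up to two frames
at 20 Hz).  All three operations are linear and are also exposed as
column-wise scikit-learn transformers.

## Shuffle test

Observed statistics are the max and min of the event-triggered average in
a window of 1.5 s beginning 0.25 s before onset (grooming additionally
uses a 4.25 s window for sustained activity).  Each of the 1000 shuffles
draws the same number of pseudo-onsets uniformly (with replacement, no
minimum separation) among frames of the valid periods whose full window
fits in the recording.  "Outside 95% of the shuffles" is implemented as
two one-sided tests at α = 0.05 each — max against the 95th percentile of
shuffled maxima, min against the 5th of shuffled minima — matching the
separate excited/inhibited calls; a split-α (97.5/2.5) variant is exposed.
Quantiles use the inclusive (type-7) convention and significance requires
strict inequality, so an all-constant trace is never significant.  Tests
with fewer than three events are flagged `low_n`.  No multiple-testing
correction is applied across cells (configurable off by default, matching
the protocol the test reimplements).

A cell flagged in both directions — which genuinely happens when a
tonically active, stop-suppressed cell sits above the session average just
before stops — is assigned the direction whose observed statistic is more
extreme against its null: first by shuffle percentile, then (because
percentiles saturate at 100 with 1000 shuffles) by exceedance over the
null mean in null SDs.  Conflicts are logged.

Calibration: on noise-only cells with 60 genuine stop times, both flag
rates measure ≈ 0.05, as recomputed by `scripts/acceptance.py`.

## Activation probability

An event is "coded" when its window peak exceeds the baseline mean plus
5 baseline SDs.  The baseline is every frame outside all event windows
(within the valid periods), further excluding a 2 s margin (≈ 4 decay
constants) after each window: a slow indicator's transients decay well past
the analysis window, and without the margin the evoked tails of a reliable
cell inflate the baseline SD enough to mask its own responses.  The margin
is a parameter (`baseline_exclude_margin_s`), and an explicit
`baseline_frames` argument overrides the default entirely.  Peaks are
taken on the smoothed trace by default (raw is configurable).

## Exact composition test

The Freeman–Halton r×c test enumerates every nonnegative integer table
with the observed margins and sums the multivariate-hypergeometric
probabilities of tables at most as probable as the observed one
(log-probabilities via lgamma; ties admitted within 1e−12 in log space).
Enumeration is exhaustive and exact for totals up to a configurable bound
(default 200; beyond it the test refuses rather than approximates).
All-zero rows/columns are dropped with a warning.  For 2×2 tables this
reduces to the classical two-sided Fisher exact P.

## Decoding

Features default to smoothed ΔF/F (raw or deconvolved are configurable).
Labels are walking (forward) = 1 vs stationary = 0; backward frames are
ambiguous for that dichotomy and are excluded with a count.  The
classifier is a linear SVM (hinge loss, L2 penalty, class-balanced
weights, C = 1 fixed — no tuning).  Validation draws five random
*contiguous* 20% test chunks (train on the remainder); contiguity limits
temporal leakage through calcium autocorrelation, which i.i.d. frame
splits would inflate.  Splits lacking either class are redrawn (logged);
ROC/AUC per split comes from sweeping all decision-value thresholds
(trapezoid rule, equal to the Mann–Whitney normalization).  A stop is
"unpredicted" when the full-data fit predicts no stationary frame within
1.5 s after its onset — the criterion for an unpredicted event is a
documented package choice.

## Pipeline and reproducibility

`run_pipeline` executes simulate → detect → process → test → classify →
decode and writes a bundle of CSV/JSON outputs plus a run log with every
resolved parameter.  All randomness derives from named `SeedSequence`
children of the config seed (one stream per cell, per analysis, per
shuffle set), so outputs are byte-identical for a fixed config.  Problem
sizes used by the validation studies: 400 s sessions (≥ 60 stops) for
shuffle-test calibration (200 null cells) and power (100 seeds); 800 s
(first 100 stops) for activation-probability recovery at reliabilities
0.2/0.5/0.8; fifty 150 s simulations for the detection round trip; 600 s
with 8 sustained reliability-0.9 cells for decoding (20 label-permuted
controls); and the default 600 s / 20-cell cohort for end-to-end class
recovery.

## Known limitations

- The shuffle null assumes the trace is statistically homogeneous over the
  valid periods; strong slow drift would mis-calibrate both tails.
- Uniform pseudo-onsets ignore the non-overlap structure of real events;
  at the event densities studied here this measurably does not affect
  calibration, but extremely dense event sets could.
- The Freeman–Halton enumeration is exponential in table size; it is meant
  for the small group×class tables of this design, not for large tables.
- Cross-session cell identity is taken as given (shared cell ids); no
  contour alignment is performed.
- Treadmill-context stops are expected to come from manual annotation;
  the detector is built for open-field oriented-speed traces.
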