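# Methods

## Scope and model

The package reimplements, as a reusable and testable pipeline, the
computational analyses used to validate engineered motor-neuron/myotube
co-cultures: multi-unit spike detection on MEA recordings, network-burst
detection from the population firing-rate histogram, culture maturity
staging, and quantification of myotube contraction before and after
nicotinic acetylcholine-receptor blockade with α-bungarotoxin. No
biophysics is simulated: neurons and myotubes enter only through the
statistical structure of the event streams they produce.

All times are seconds (floats), all interval conventions half-open
`[start, end)`, with one time origin per recording (t = 0 at recording
start) and per assay window.

## Spike detection

- **Filter.** Butterworth bandpass, order parameter 4 in the bandpass
  design call (8 poles overall), corners 300 and 3,000 Hz. Applied
  zero-phase (forward–backward, `sosfiltfilt`) by default so detected
  timestamps carry no systematic group delay into the 50 ms bins
  downstream; the effective magnitude response is then the square of the
  single-pass design, and `analytic_gain` reports the response of
  whichever mode is configured. Single-pass filtering is available via
  `FilterSettings(zero_phase=False)`.
- **Threshold.** Per electrode, mean and SD are estimated over the
  *entire* filtered trace (a robust median-based estimator is available
  but off by default), and samples deviating more than `threshold_sd`
  (default 7) SDs from the mean are excursion samples. The rule is
  two-sided (absolute deviation from the mean — the literal reading of
  "deviation from the mean signal"); a negative-only mode is provided
  since extracellular spikes are dominantly negative and the original
  polarity convention is not documented.
- **Dead time.** Exceeding samples within `dead_time` (default 1 ms) of
  the previous exceeding sample extend the current event; a new event
  opens only after a longer gap. The event timestamp is the first
  excursion sample. This gap-based rule ensures one timestamp per
  biphasic waveform even when the filtered spike's above-threshold
  support spans slightly more than the dead time; it is mirrored exactly
  by the brute-force scan oracle in the test suite.
- **Degenerate input.** A constant trace yields an empty train with a
  logged warning (constant traces are detected by zero peak-to-peak
  range, since floating-point roundoff can leave the computed SD slightly
  nonzero). Detection is invariant to constant offsets and to positive
  rescaling.

## Network activity

- **Histogram.** Spikes from all electrodes are counted in 50 ms
  half-open bins; a spike at exactly the recording end is assigned to the
  last bin so the histogram always conserves the total spike count.
- **Burst threshold.** mean + 5·SD of the histogram, computed over all
  bins of the recording *including empty bins* and computed once, before
  participation pruning. The comparison is strict (`>`), so a perfectly
  flat histogram (SD = 0) yields no bursts.
- **Active electrodes.** An electrode is active at recording level when
  its individual rate is ≥ 0.1 Hz (inclusive boundary). The 0.1 Hz
  default is a package choice — the pruning rule needs a denominator and
  no value is prescribed — and is exposed in the config. Within a bin,
  "active" means ≥ 1 spike in that bin; the two senses are deliberately
  distinct.
- **Pruning.** A candidate bin survives when the number of recording-
  level-active electrodes firing in it is ≥ 20% of the active set
  ("fewer than 20%" prunes, so exactly 20% survives). An empty active
  set prunes everything and logs a warning.
- **Merging.** Runs of consecutive surviving bins become single bursts;
  boundaries snap to bin edges, so burst durations are positive
  multiples of the bin width and no two bursts occupy adjacent bins
  (merging is idempotent by construction). Per-burst spike counts are
  the histogram sums over the merged bins, which — both being half-open
  on the same grid — equal a recount of raw timestamps in
  `[start, end)`.
- **Summary measures.** Network firing rate = total spikes / duration;
  burst fraction = spikes inside bursts / total spikes (0 when either is
  empty); recordings with rate < 0.05 Hz are flagged for exclusion
  (strict `<`; the default mirrors discarding near-silent early
  cultures).
- **Staging.** young 15–35 DIV, middle-aged 42–56 DIV, old 63–70 DIV,
  inclusive bounds; the gaps (36–41, 57–62) and everything outside map
  to `unstaged` rather than to the nearest stage, to avoid inventing
  boundaries that were never stated. The nine recording days
  {15,22,28,35,42,49,56,63,70} therefore partition 4/3/2.

## Contraction assay

- **Selection.** "More than 1 contraction per minute over 5 min" is read
  as a strict mean (> 5 events in 5 min) *and* ≥ 1 event in each 1-min
  bin; both clauses are enforced. Windows shorter than the observation
  period are rejected.
- **Counting and binning.** 10-min counts over `[0, 600)` s of each
  named window; 30-s half-open bins whose sum equals the window count by
  construction. Percent reduction is 100·(1 − post/pre), undefined
  (rejected) for pre = 0, and may be negative when activity increases.
- **Classification.** `abolished` requires post = 0; otherwise the
  reduction is compared with a ±10% tolerance for
  `reduced`/`unchanged`/`increased`. Only abolition is grounded in the
  reference outcomes; the remaining class boundaries are package-defined
  and exposed in the config.
- **Partial contractions.** An optional per-event flag; partial events
  are tallied separately (`count_partial`, `pre/post_partial_count`) and
  never merged into full-contraction counts, preserving the distinction
  without inventing a weighting.

## Synthetic data generators

All generators are pure functions of (parameters, seed) using one
`numpy` PCG64 stream per call; identical calls are bit-identical.

- **Raw traces.** I.i.d. Gaussian noise (default SD 5 µV — a free
  parameter, since no noise statistics are documented for the original
  hardware, chosen as a plausible in-band extracellular noise floor)
  plus a biphasic negative-then-positive template of 1.5 ms total
  duration (one sine cycle, scaled so the negative peak equals the
  requested amplitude) added at scheduled times. Default 10 kHz, 240 s.
  The generator emulates threshold-crossing structure only: no spike-
  shape variability, no electrode cross-talk, no drift or line noise —
  so passing recovery tests demonstrates correctness of the detection
  rules, not robustness to every artifact of real recordings.
- **Spike trains.** Homogeneous Poisson background per electrode
  (sampled as a Poisson count plus sorted uniforms). Each planted burst
  epoch recruits a freshly drawn `participation` fraction of electrodes
  (re-drawn per epoch, matching the variability of real network bursts
  without extra parameters) and superposes an extra Poisson process at
  `background·(multiplier − 1)` inside the epoch — exactly the target
  piecewise-homogeneous Poisson process. Overlapping epochs are
  rejected. Real bursts have ramped onsets and within-burst temporal
  structure; the generator's rectangular rate profile is deliberate, as
  it makes ground-truth recovery unambiguous.
- **Contractions.** Poisson event streams (rates in events/min) thinned
  by a refractory period (default 1 s — a myotube cannot re-contract
  instantaneously), separately for the pre and post windows. The kept
  process is a renewal process with interarrival `refractory +
  Exp(rate)`, which the test suite exploits as an independent
  Monte-Carlo oracle: for the study's rate pair (12.4 → 1.1 per min,
  600 s windows) the oracle gives a mean percent reduction of 89.4
  (single-series SD 3.3), and the implementation is required to
  reproduce it within Monte-Carlo error over 200 seeds.

## Validation strategy and problem sizes

Every detection stage is checked two ways: against hand-constructed
cases whose outcome is forced by the rules, and against independent
brute-force oracles (a sample-by-sample threshold scan; a bin-by-bin
mark/prune/merge loop; event-by-event recounts) on randomized inputs.
Planted-structure recovery runs at the study's recording scale where
that is cheap (spike trains: 60 electrodes × 240 s) and on shorter
multichannel traces where raw-signal processing dominates (raw
fixtures: 2–8 electrodes × 5–20 s at the full 10 kHz), sizes chosen so
the whole suite runs in well under a minute while keeping every rate,
threshold and SNR at its study value. Planted burst epochs in the
recovery fixtures start on whole seconds (and hence on 50 ms bin
edges); recovery with off-grid epochs is exercised separately in the
burst-fraction tests.

## Known limitations

- SD-based thresholding is biased upward by high firing rates (spikes
  inflate the trace SD); the robust estimator option mitigates this but
  is off by default to match the plain rule.
- The burst detector's mean + 5 SD threshold adapts to the recording;
  recordings dominated by burst bins (bursty time ≫ a few percent)
  raise their own threshold and can mask genuine epochs. This is a
  property of the published rule, not of the implementation.
- No spike sorting: electrodes are analysed as multi-unit channels.
- Contraction input is an event list; detecting contractions from video
  is out of scope.
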