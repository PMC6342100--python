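# Methods

## The classification problem

A collar-borne logger on a small mammal records tri-axial acceleration
(±8 g) and temperature at 1 Hz for weeks to months.  The task is to turn
that stream into a per-second behavioral record at a chosen level of
detail: in/out of the thermal refuge (nest), moving vs not moving, and —
among out-of-nest movement — feeding, foraging (slow locomotion while
searching and handling food) and running.  At 1 Hz there is no usable
frequency content (stride frequencies of a ~250 g animal alias far below
Nyquist), so the method relies on windowed amplitude statistics of the
*dynamic* acceleration and on collar temperature, not on spectra.

## Pipeline

1. **Static/dynamic separation.**  Gravity and posture form a slowly
   varying component estimated by a centered running mean over 91 s
   (configurable).  Dynamic acceleration is raw minus static, per axis.
   Edges use symmetrically truncated centered windows, so day boundaries
   keep full-length output; reconstruction raw = static + dynamic holds to
   one floating-point rounding.  Temperature is pre-filtered with a 5-s
   centered rolling median, which removes single-sample sensor glitches
   while leaving monotone warming/cooling ramps untouched.  (The median is
   this package's choice of glitch filter; window configurable.)

2. **Nest gate.**  For each noon-to-noon day, smoothed temperatures are
   split into two clusters by an exact 1-D 2-means — the global optimum is
   found by scanning the split point on the sorted values, so there is no
   initialization or seed sensitivity — and the day's threshold is the
   midpoint of the two cluster centers (midpoint chosen over the cluster
   boundary; the two rarely differ materially and the midpoint is robust
   to unequal cluster spreads).  A day whose centers are separated by less
   than 4 °C is *degenerate*: an insulated occupied nest raises collar
   temperature by ~10–20 °C, while carving up ambient variation alone
   (e.g. a diurnal cycle, whose marginal distribution is bimodal by
   itself) produces gaps of only a couple of degrees.  Degenerate days
   inherit the nearest valid day's threshold with a warning; if no day is
   valid the detector classifies everything out-of-nest rather than
   guess.  Finally, any in-nest bout in which moving seconds strictly
   outnumber not-moving seconds is reclassified out-of-nest (nests are
   used for rest; a "warm but busy" bout is more plausibly sun or
   activity), and adjacent same-state bouts re-merge.  The correction is
   idempotent.  No minimum bout duration is imposed.

3. **Movement gate.**  Delta-DBA over a window of t samples is
   Σ_{i=2..t} (|Δdx_i| + |Δdy_i| + |Δdz_i|) — t−1 difference terms, all
   inside the window so tiled windows stay independent.  Non-overlapping
   14-s windows tile the trace; a window is *moving* when its delta-DBA
   strictly exceeds the gate threshold (default 1.06 g, the published
   field calibration).  The gate is calibrated for a new device family as
   the 99.9% empirical quantile (linear interpolation) of windowed
   delta-DBA from motionless devices.  The same gate runs inside the
   nest, yielding in-nest moving / in-nest not-moving.

4. **ODBA split (10 s).**  Out-of-nest moving segments are re-tiled into
   10-s windows; window ODBA (Σ |dynamic| over samples and axes) strictly
   above the threshold (default 6.2 g) means traveling, else feeding.
   Side assignment (traveling = high) follows the amplitude ordering of
   the signatures — locomotion moves the whole body, food handling does
   not — and is configurable.

5. **Surge split (4 s).**  Traveling spans are re-tiled into 4-s windows
   (the natural duration of a running bout); max dynamic surge strictly
   above the threshold (default 1.15 g) means running, else foraging.

Windows at each stage tile from the start of the parent-stage segment;
per-second labels inherit from the innermost stage that classified them.
A trailing remainder shorter than half the nominal window inherits the
preceding window's label; one at least half-length is classified on its
own statistic prorated to the nominal window — delta-DBA by difference
terms ((t_full−1)/(t_partial−1)), ODBA by sample count; a maximum needs
no proration.  All threshold comparisons are strict `>`; values exactly
at a threshold take the low branch.

The four levels of output labels nest exactly: every level-6 label has
one parent at levels 5, 4 and 2, so classifying at level 6 and
aggregating equals classifying at the coarser level directly (asserted in
tests).  Stationary movement (grooming, vocalizing) is a valid
observation category but not a tree leaf; it aggregates to moving /
out-of-nest and is excluded from finer-level scoring.

## Calibration from observations

Training windows are selected from time-aligned behavioral observations
under purity rules: a window counts as feeding only if 100% of its
seconds were feeding; as foraging if ≥75% were foraging with 0% running;
as running if ≥51% were running (running rarely outlasts the window).
Each binary split's threshold is the argmax of a balanced-accuracy scan —
candidates from min to max of the statistic at 0.01 g steps; the score is
the unweighted mean of the two per-class accuracies (matching the
equal-n training design); ties resolve to the lowest candidate; the
orientation (which class is "above") is chosen to maximize the score.
The surge calibration by default uses only segments that the
freshly-calibrated ODBA split classifies correctly as traveling
(hierarchical cleaning, its statistic prorated across window lengths).

`histogram_compare` ranks all 25 statistics by the balanced accuracy of
their best single threshold, reproducing the visual
histogram-then-optimize workflow as a number.

## The 25 window statistics

Per axis on dynamic acceleration: mean, SD (n−1 denominator), max, sum,
range, sum of |Δ| — 18 statistics.  Cross-axis: ODBA, delta-DBA, min and
max of the per-sample summed |Δ|, max per-sample total |dynamic|
("maximum acceleration"), and mean pitch/roll in degrees from the static
components (pitch = atan2(g_x, √(g_y²+g_z²)), roll symmetric) — 7 more,
25 in all.  Axis sums of Δ use absolute differences (consistent with
delta-DBA).  Pitch/roll feed only the random-forest benchmark; the manual
tree uses dynamic acceleration exclusively.

## Clock alignment

Observation devices and loggers drift apart by seconds, which matters for
second-scale behavior.  The per-second activity series a(i) =
Σ_axes |d(i+1)−d(i)| yields onset events (start of ≥3 s sustained above
0.5 g, timed at the first active sample) and offset events (start of a
sustained quiet run, timed at the first quiet index); events within 10 s
of the previous are suppressed.  The observation-side events are
rest↔travel boundaries inside continuous observation.  A 1-s grid search
over shifts in ±60 s scores each shift by direction-matched pairs within
±2 s, weighted triangularly (3, 2, 1 for |Δt| = 0, 1, 2): the weighting is
needed because the raw pair count plateaus across the whole tolerance
band and accidental matches at the plateau edge otherwise bias the argmax
by ±1 s; with it, injected integer offsets are recovered exactly in ≥95%
of simulated runs.  Observation days with no abrupt transition cannot be
aligned and are rejected (a value, not an exception), mirroring their
exclusion from downstream analysis.  A constant offset per observation
day is assumed; oscillator drift within a minutes-long focal is
negligible.

## Evaluation

Accuracy is scored on observation *events* (intervals of continuous
observed behavior): an event is correct when the modal predicted label
over its span equals the observed label at the requested level.  Modal
(event-level) scoring is used at both resolutions for consistency.  Per
class, events are subsampled without replacement (default 50 per class,
100 repetitions) and means ± SD reported; "overall" is the unweighted
mean of class means.  In-nest accuracy cannot come from focal events
(observers cannot see into a nest): nocturnal 15-s samples between 22:00
and 04:00 are labeled in-nest by assumption for a diurnal nest-sleeping
animal (`night_nest_check`, `augment_with_night_nest_events`).  The
low-resolution check scores 7-min scans on their inner 5 minutes, with
traveling defined as any mix of foraging and running.  Daily time budgets
are proportions of classified seconds per calendar day (partial first and
last days excluded; unclassified seconds reported separately), with
seasonal summaries over configurable date windows (defaults: Feb 15–25,
Mar 10–20, Jun 10–20, Sep 5–15).

## Random-forest window benchmark

For each window length in {2, 4, 7, 10, 14, 20, 30} s: select training
windows under the purity rules, balance classes by subsampling to the
rarest class, fit a random forest (default 2,000 trees, 75/25
train/holdout; other hyperparameters at sklearn defaults) on the 25
statistics and report per-class and overall holdout accuracy, plus the
mean classified bout duration per class from tiling the whole trace
(movement-gated with the delta-DBA threshold prorated to the window).
Additions for reliability at small pools: `n_splits` re-draws the
train/holdout split and averages (pools ≥500/class use one split);
per-window RNG streams make each window's result independent of which
other windows are swept; `bout_windows` restricts the (expensive) bout
diagnostic.

On simulated data the benchmark reproduces two of the three published
qualitative findings robustly: accuracy rises steeply from the 2-s window
to a mid-length optimum, and classified bout durations inflate roughly
linearly with window length (tiled windows quantize bouts).  The third —
a decline at the longest (30 s) window — does not emerge in expectation
here: with stationary per-second emissions the discriminability of window
statistics is non-decreasing in window length, so the decline can only
come from training-pool scarcity at 30 s, where it is smaller than the
holdout-estimate noise.  A decline of that kind is a property of real
field data (non-stationary behavior, observation error, a single small
holdout) that this simulator deliberately does not model; the
corresponding assertion in the acceptance suite documents this and is
expected to fail.

## The synthetic-data generator

The generator produces the statistical structure the classifier assumes,
not biomechanics:

* **Schedule.**  The animal nests through a nocturnal window (21:00–06:30
  by default); daytime behavior is a semi-Markov sequence over nest
  visits, out-of-nest rest, feeding, foraging and running, with the next
  state drawn with probability proportional to each behavior's remaining
  share of a configured daily time budget (default: 55% in nest, 10%
  rest, 12% feeding, 18% foraging, 5% running).  This keeps realized
  budgets near the configuration while bout durations keep their
  configured gamma distributions (field-observed means: feeding 30 s,
  foraging 10 s, running 4.5 s; dispersion is a free parameter).  Running
  bouts are capped at 10 s — sustained sprints are physiologically
  bounded — so long "running" stretches are really several bursts broken
  by slower travel.  In-nest time alternates long rest bouts with brief
  movement.

* **Emissions.**  Zero-mean Gaussian noise per behavior and axis, plus an
  alternating-sign heave component for the rhythmic handling of food
  (feeding), surge spikes at 0.35/s for running strides, and occasional
  few-second volleys of running-amplitude surge jolts during foraging
  (digging, cone handling) — a deliberate caricature of the published
  signal signatures.  Gravity contributes a constant (0, 0, 1) g static
  component.  Emissions are sampled directly at 1 Hz.

* **Temperature.**  Collar temperature relaxes (first-order, τ = 180 s)
  toward ambient — a 5 °C diurnal cycle around 5 °C — plus a +20 °C
  offset while in the nest, with 0.2 °C sensor noise and rare ±15 °C
  one-sample spikes to exercise the median filter.

* **Observations.**  Simulated focal windows (daytime, non-overlapping,
  2–12 min) excerpt the ground truth, optionally shifted by a configured
  observer-clock offset and per-day drift.

Presets: `separable` (well-separated emissions *and* bout durations long
relative to the classification windows, with a fast 60-s collar time
constant — it isolates implementation correctness from window-boundary
quantization, which is its purpose; end-to-end level-6 accuracy ≈ 98%),
`field_like` (field-observed durations and overlapping emissions;
end-to-end level-6 accuracy ≈ 82%, inside the intermediate regime a real
calibration sees), `no_temp_contrast` (zero nest offset; every day is
degenerate and nest detection must degrade gracefully), `drifted_clock`
(+3 s/day observer drift).

What passing tests on this generator do **not** show: robustness to
collar rotation or loose attachment, posture-dependent static changes,
non-stationary behavior intensity, heterothermy, real ambient weather, or
logger dropout patterns.  They do show that every rule, threshold,
window and correction behaves exactly as specified on data whose ground
truth is known.

## Numerical and design details

* Time is integer seconds since deployment start; no float-time drift.
* Gaps in a logger export become NaN rows on the grid (never
  interpolated); windows touching them are dropped and counted.
* The empirical quantile uses linear interpolation between order
  statistics; it warns below ~1,000 still windows.
* Grid scan step 0.01 g; candidate range [min, max] of the statistic.
* Degenerate-input behavior is explicit everywhere: all-equal temperature
  days, single-class calibration inputs, observation days without
  transitions, traces shorter than one window — each raises or warns as
  documented rather than returning silently wrong values.
* Problem sizes in the shipped tests and acceptance script: 10 simulated
  days for end-to-end recovery, 2 days for the field-like regime, 8-day
  deployments (3 replicates) with ~6 h of observation per day for the
  window benchmark at 200 trees, 25–50 half-day runs for clock-offset
  recovery.  These sizes give stable statistics for every reported
  quantity except the 30-s benchmark point, whose pool is intrinsically
  scarce (a few dozen windows) — as it is in the field.

## Known limitations

* The temperature glitch filter is a stand-in (the original study's
  filter is described only in unavailable supplementary material).
* The 91-s smoothing window is taken as given; its sensitivity analysis
  is out of scope, but the window is a config knob.
* Whether the field k-means ran on raw or smoothed temperature is
  unknown; smoothed, all samples, is assumed.
* The movement gate inside the nest reuses the out-of-nest threshold;
  the original routing is not stated.
* Published field thresholds (1.06 / 6.2 / 1.15 g) and accuracies are
  properties of the original field data; this package reproduces the
  *procedures* and verifies them on synthetic ground truth, not the
  field numbers.
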