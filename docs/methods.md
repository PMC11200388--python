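# Methods

`stepbench` is a software pre-validation bench for low-power wearable step
counters.  It answers the question a study team faces before any human
validation trial: *given an embedded pedometer with a threshold, a
debounce-step count, and a debounce-time window, which setting
combinations will count steps accurately over the cadence range of the
population I care about?*  The bench replaces the mechanical
continuous-stepper rig used for this purpose — a motor-driven cam that
drops two pistons onto foam while an optical distance sensor watches the
cam fins — with a seeded simulator, and then runs the same analysis
pipeline a hardware bench would: collect trials, compute ground truth,
model error, optimize settings.

## The simulated rig

`generate_optical_trace` and `generate_impulse_train` share one step
clock: steps occur at t = k·60/cadence s for k = 1…⌊duration·cadence/60⌋
(no event at t = 0, so the count is exactly the floor expression).  Steps
alternate left/right starting left.

The optical trace samples at 100 Hz.  Each step contributes a rectangular
voltage peak on the 7 samples before its impact sample — 1.5 V for left,
2.5 V for right over a 0 V baseline.  Seven samples (70 ms) is the
assumed dwell of a fin in front of the distance sensor; the width must
exceed the largest moving-mean window the ground-truth loop reaches on
realistic traces (see below) and stay well under the shortest inter-step
interval (545 ms at 110 steps/min).  Optical glitches are Poisson-placed
single-sample spikes on baseline samples (a glitch during a fin passage
would merely saturate an already-high reading).

The impulse train carries one acceleration peak per step, nominally 1.1 g
(the impact of a 2.5 kg piston dropped a few centimetres onto foam, which
is representative of foot strike at walking speeds).

### Default noise conditions

The `NoiseSpec` defaults model a well-built rig, and were fixed once from
the rig's physics:

| parameter              | default | unit  | rationale |
|------------------------|---------|-------|-----------|
| `timing_jitter_sd_s`   | 0.02    | s     | a DC-motor cam holds cadence to roughly 1–2 % of a ~1 s step interval |
| `amplitude_jitter_sd_g`| 0.05    | g     | ~5 % impact-to-impact variability on foam |
| `spike_rate_per_min`   | 2       | 1/min | a handful of optical glitches per trial |
| `spike_amplitude_v`    | 3.0     | V     | glitches saturate above both quantization bands |

What the generator deliberately does **not** emulate: human stride-time
variability (the rig is metronomic by design), speed-dependent impact
attenuation (impacts are gravity-driven at every cadence), non-step body
noise such as weight shifts, and any internal decimation or binning of
the sensor firmware.  Passing tests therefore validate the *method* —
state machine, ground-truth pipeline, model, optimizer — on rig-like
data; they do not certify accuracy on free-living human data.

## The pedometer state machine

`count_steps` implements the documented debounce semantics.  While
DEBOUNCING, consecutive above-threshold impulses each arriving within the
debounce window accumulate; reaching the debounce-step count promotes the
bout to COUNTING and credits the accumulated impulses retroactively (a
fully connected bout of 12 impulses yields 12 steps; `retroactive=False`
gives the stricter alternative in which only the promoting impulse is
credited).  While COUNTING, each impulse within the window adds one step;
a longer gap closes the bout.  A long gap while debouncing discards the
accumulated impulses.

Two deliberate choices:

* **Inclusive gap comparison** (gap ≤ window passes, with a 1 ns slack
  against float round-off).  A metronomic 30 steps/min train (2 s gaps)
  is then fully captured by a 2000 ms window, and
  `min_detectable_cadence(w) = ⌈60000/w⌉` exactly.
* **A bout needs at least two connected impulses**, even at
  `debounce_steps = 1`.  Without this, a single impulse would
  self-promote and every isolated jolt would count as a one-step bout,
  making the debounce window inert at that setting (and, in simulation,
  making `debounce_steps = 1` settings spuriously error-free at any
  window).  With it, a regular train whose gap exceeds the window yields
  zero steps at every setting — e.g. nothing below 60 steps/min is
  detected with a 1000 ms window.

## Ground truth from the optical trace

The reference count never comes from the simulator's bookkeeping; it is
recomputed from the voltage trace, as a hardware bench must:

1. **Quantize**: ≥ 2 V → 2 (right), ≥ 1 V → 1 (left), < 0.5 V → 0.
   Voltages in [0.5, 1) V are a dead band mapped to 0 and logged; the
   simulated hardware never emits them, but real imports might.
2. **Smooth**: centered moving mean, any non-whole-number output replaced
   with 0.  The filter runs on each foot's *binary indicator* separately.
   Smoothing the combined {0,1,2} sequence is unsound: for every even
   window w, a window half-overlapping a right-foot plateau sums to
   2·(w/2) = w — an exactly whole mean of 1 — fabricating a left-foot
   peak beside every right-foot peak, so successive window sizes could
   never agree.  A binary indicator's mean is whole only at full overlap:
   peaks shrink by w−1 samples, never change sides, and runs shorter than
   the window are deleted.  Implemented in exact integer arithmetic
   (sum mod w), zero-padded at the edges (suppresses, never creates,
   peaks); even windows use numpy's half-sample-offset centering.
3. **Count peaks**: one per maximal constant nonzero run; runs of
   different values touching without a 0 split at the change.
4. **Enforce alternation**: feet must go 1-2-1-2; when a side repeats,
   the later occurrence is removed as an artifact (the earlier peak
   anchors the alternation already established; a drop-earlier variant
   would only matter for pathological traces).
5. **Converge**: starting at a 3-sample window, compare the corrected
   count at w and w+1; equal ⇒ done, else grow by one sample.  A cap of
   25 samples bounds the loop; hitting it raises `ConvergenceError`
   naming the trial.

On noise-free traces the loop converges at the first comparison and
equals the generator's step log exactly; single-sample spikes (tested to
10/min) never change the converged count.

Signed trial error is (sensor − truth)/truth: −0.10 means 10 % of steps
missed, +0.10 means 10 % overcounted.

## Experiment design

`run_experiment` runs each setting × cadence trial with per-trial seeds
derived from the run seed via `SeedSequence([run_seed, trial_index])`, so
any single trial is reproducible from its recorded seed.  Two cadence
protocols exist: an explicit list (full Cartesian design), and
`"low-high"`, which draws one low (30–69) and one high (70–110) integer
cadence per setting.  The low-high protocol mirrors how a hardware bench
spreads speeds over collections, and it matters statistically: with only
two fixed cadences in the whole design, every cadence monomial above
first order is collinear and the regression could never resolve the
cadence axis.

The bench-scale design subsamples the 7595-point grid with strides
(2, 4, 5) on (debounce steps, debounce time, threshold) — 224 settings,
each at two cadences: 448 trials.  Default trial duration is 2700 s (the
bench's 45 min trials); the test suite and worked examples use 60 s
trials, which bound the per-trial error resolution at 1/30 at the slowest
cadence and keep a full run under a minute.

## Error model

Signed error is regressed on the complete monomial basis (total degree
≤ d) of the four min–max-normalized predictors — threshold (32–996 mg),
debounce time (80–2480 ms), debounce steps (1–7), cadence (30–110
steps/min), in that fixed component order.  Normalization bounds are the
grid extremes, not the observed data, so predictions over the whole space
stay on [0,1]⁴.  Orders 1–5 are compared on R², in-sample RMSE,
10-fold seeded CVMAE (fractional units, also reported ×100 as
`cvmae_pct`), and the fit gap (test − train RMSE under a seeded 90/10
split; positive ⇒ overfitting).  Selection: highest R² among orders that
are not rank deficient and whose fit gap is ≤ 0.05; R² ties (within
1e−9) break to the lowest order.  OLS uses a rank-revealing SVD solver;
rank deficiency is flagged, reported, and excludes the order from
selection.

A structural fact worth knowing: the stride-2 subsample leaves only four
debounce-step levels {1,3,5,7}, so the pure quartic in that variable is
exactly collinear with its lower powers and orders 4–5 are rank deficient
*by design* on the 448-trial layout.  On such data the admissible model
is at most cubic.

## Optimizer

For a cadence range, predictions are made at every integer cadence; AE is
the mean |error| (a signed-mean mode exists, but a signed AE would reward
large undercounts), STD the sample (n−1) standard deviation of signed
errors, and the composite score w·AE + (1−w)·STD is minimized over all
7595 settings.  w is required in config and echoed in every report;
default 0.5 (no stated reason to prefer accuracy over consistency
a priori).  A setting is within tolerance only if |predicted error|
≤ 0.10 at *every* integer cadence — the strictest reading of keeping
error within ±10 % across a range.  Ties in the composite break by
(STD, AE, threshold, debounce time, debounce steps).  An empty
within-tolerance set is a structured warning carrying the best
out-of-tolerance candidates, not an error.

The preset ranges are 30–60 steps/min (disabled low-mobility
ambulators), 30–90 (disabled high-mobility) and 30–110 (healthy).

## Known limitations

* The debounce mechanism is a knife edge at the slow corner: at cadence
  30 the error surface jumps from roughly −0.5 at a 2000 ms window (half
  the jittered 2 s gaps fail, and each failure discards a partial bout)
  to ≈ 0 at 2320 ms.  A cubic — the highest admissible order on the
  strided design — cannot keep |prediction| ≤ 0.10 at that corner while
  also tracking the much sharper high-cadence cliff, so wide ranges
  (30–110, sometimes 30–90) can end with an empty within-tolerance set
  even though settings with near-zero simulated error exist; the 30–60
  range reliably yields recommendations with debounce times ≥ 2000 ms.
  Real firmware appears softer than the idealized mechanism, which is
  one reason hardware benches report within-tolerance settings at
  windows our state machine would call lossy.
* Rank deficiency of orders 4–5 is a property of the strided design, not
  of the method; denser debounce-step sampling would admit them.
* The grid of 35 threshold values is uniform 32–996 mg; real register
  spacing is unstated and can be swapped in via
  `stepbench.settings.THRESHOLD_MG_GRID`.
* The alternation check assumes a two-foot rig; it is not a general
  artifact rejector.
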