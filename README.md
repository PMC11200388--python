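# stepbench

Software pre-validation of step-count sensor settings.

Low-power wearable activity monitors count steps with an embedded
three-knob algorithm: an acceleration **threshold** (mg) an impulse must
reach, a **debounce step** count of consecutive impulses required before
a bout is accepted as walking, and a **debounce time** window (ms) within
which the next impulse must arrive.  On the LSM6DSL-class parts this
gives 35 × 7 × 31 = 7595 setting combinations — far too many to test on
human subjects, yet the choice dominates accuracy at slow walking
speeds, exactly where clinical populations walk.

`stepbench` reproduces, fully in software, the mechanical bench used to
choose these settings before human validation:

1. **Simulate** a continuous-stepper rig (seeded): an optical
   distance-sensor voltage trace at 100 Hz plus a ~1.1 g foot-impact
   impulse train, at any cadence in 30–110 steps/min.
2. **Ground truth**: the voltage trace is quantized (1 = left foot,
   2 = right), cleaned with a moving-mean filter that deletes
   non-whole-number outputs, checked against the expected 1-2-1-2
   alternation, and the filter window grows until two successive
   corrected counts agree.
3. **Sensor count**: a deterministic state machine applies the
   threshold/debounce semantics to the impulse train.  Trial error is
   (sensor − truth)/truth.
4. **Model**: multivariate polynomial regression (orders 1–5, complete
   monomial basis) of error on the normalized threshold, debounce time,
   debounce steps and cadence; order chosen by R² among
   non-rank-deficient fits with an acceptable train/test RMSE gap,
   with 10-fold CVMAE reported.
5. **Recommend**: for a cadence range [lo, hi], every setting is scored
   over all integer cadences with

   *Composite = w·AE + (1 − w)·STD*,

   where AE is the mean |predicted error| and STD the standard deviation
   of predicted errors; candidates must keep |error| ≤ 10 % at every
   cadence.  Preset ranges: 30–60 (disabled low-mobility ambulators),
   30–90 (disabled high-mobility), 30–110 steps/min (healthy).

The trial-record CSV (`threshold_mg, debounce_steps, debounce_time_ms,
cadence_spm, true_steps, sensor_steps, error_frac, seed`) is the contract
between simulation and modelling — tables from real hardware runs can be
fed to `fit`/`recommend` unchanged.

See `docs/methods.md` for the model details and design rationale.

## Worked example

A reduced bench run (224 settings × 2 seeded cadences per setting, 60 s
trials, default rig noise) through the CLI:

```sh
stepbench simulate -c config.yaml -o trials.csv
# wrote 448 trial records to trials.csv
stepbench fit trials.csv -c config.yaml -o model.json --diagnostics diag.csv
# selected order 3 (R²=0.833, RMSE=0.200); model written to model.json
stepbench recommend model.json -c config.yaml -o rec/
# 30-60 steps/min (disabled low-mobility): best threshold 32 mg, 7 steps,
#   2480 ms (composite 0.0296)
```

where `config.yaml` is the default `RunConfig` with `duration_s: 60` and
`seed: 7`.  The per-order diagnostics (`diag.csv`):

```
degree,n_terms,r_squared,rmse,cvmae,cvmae_pct,fit_gap,rank_deficient
1,5,0.703205,0.266127,0.222817,22.281717,-0.004631,False
2,15,0.747074,0.245673,0.203125,20.312520,-0.010365,False
3,35,0.832816,0.199737,0.169038,16.903778,0.045506,False
4,70,0.871523,0.175095,,,,True
5,126,0.909398,0.147038,,,,True
```

Orders 4–5 are rank deficient on this design (the stride-2 subsample has
only four debounce-step levels, so the quartic term is collinear), so the
cubic wins on R².  The 30–60 steps/min recommendation is physically
sensible: at 30 steps/min a step arrives every 2 s, so only debounce
times ≥ 2000 ms capture the slowest walkers, and the top candidates all
sit at 2480 ms with low thresholds.  For the widest range (30–110) no
setting keeps the *modelled* error inside ±10 % at every cadence — the
cubic underfits the sharp error cliff at the slow-cadence corner — so the
command reports the best out-of-tolerance candidates and exits with
code 2 (see the limitations section of `docs/methods.md`).

The same pipeline is available as library calls
(`stepbench.run_experiment`, `stepbench.select_order`, `stepbench.fit`,
`stepbench.recommend`).

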