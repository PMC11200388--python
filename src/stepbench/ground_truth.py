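"""Ground-truth step counting from the optical trace, and the trial runner.

The reference count for each trial comes from the distance-sensor voltage
trace, not from the simulator's bookkeeping, via a five-stage pipeline:

1. **quantize** — voltages become labels over {0, 1, 2}: 1 for a
   left-foot peak (>= 1 V), 2 for a right-foot peak (>= 2 V), 0
   otherwise.  Voltages in the [0.5, 1) V dead band also map to 0 (the
   band is logged; hardware never emits it with the default amplitudes).
2. **smooth** — a centered moving-mean filter per foot indicator; any
   output that is not a whole number is replaced with 0.  Single-sample
   glitches are thereby deleted while genuine multi-sample peaks survive
   with a shortened plateau (see :func:`smooth` for why the filter runs
   per side rather than on the combined label sequence).
3. **count_peaks** — one peak per maximal constant nonzero run.
4. **enforce_alternation** — feet must alternate 1-2-1-2; when a side
   repeats, the later occurrence is removed as an artifact.
5. **converged_count** — the filter window grows one sample at a time
   until two successive corrected counts agree; that count is the ground
   truth.

Sensor error for a trial is (sensor − truth)/truth: negative means missed
steps, positive means overcounting.

:func:`run_experiment` runs the whole bench — stepper simulation, ground
truth, pedometer — over a list of settings and cadences, emitting the
trial-record table that is the contract between simulation and modelling
(and the ingestion point for real hardware runs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .pedometer import simulate_sensor
from .settings import SensorSettings
from .stepper import CLEAN, NoiseSpec, OpticalTrace, generate_impulse_train, generate_optical_trace

log = logging.getLogger(__name__)

DEFAULT_LOW_CUT_V = 0.5
DEFAULT_CLASS_CUT_V = 1.0
DEFAULT_BAND_SPLIT_V = 2.0
DEFAULT_WINDOW_START = 3      # samples (0.03 s at 100 Hz)
DEFAULT_WINDOW_CAP = 25       # safety bound on window growth

#: Columns of the trial-record CSV contract.
TRIAL_COLUMNS = (
    "threshold_mg", "debounce_steps", "debounce_time_ms", "cadence_spm",
    "true_steps", "sensor_steps", "error_frac", "seed",
)


class ConvergenceError(RuntimeError):
    """The window-growing ground-truth loop failed to stabilize."""


@dataclass(frozen=True)
class LabelSequence:
    """Per-sample step labels over {0, 1, 2}."""

    labels: np.ndarray
    sample_rate_hz: float


@dataclass(frozen=True)
class GroundTruthCount:
    steps: int
    window_used: int
    iterations: int
    repeats_removed: int


def quantize(
    trace: OpticalTrace,
    low_cut: float = DEFAULT_LOW_CUT_V,
    class_cut: float = DEFAULT_CLASS_CUT_V,
    band_split: float = DEFAULT_BAND_SPLIT_V,
) -> LabelSequence:
    """Threshold voltages into {0, 1, 2} labels."""
    if not (0 < low_cut < class_cut):
        raise ValueError("need 0 < low_cut < class_cut")
    v = trace.voltages
    labels = np.zeros(len(v), dtype=np.int64)
    labels[v >= class_cut] = 1
    labels[v >= band_split] = 2
    n_dead = int(np.sum((v >= low_cut) & (v < class_cut)))
    if n_dead:
        log.debug("%d samples in the [%g, %g) V dead band quantized to 0",
                  n_dead, low_cut, class_cut)
    return LabelSequence(labels=labels, sample_rate_hz=trace.sample_rate_hz)


def smooth(labels: LabelSequence, window: int) -> LabelSequence:
    """Centered moving mean; non-whole-number outputs replaced with 0.

    The filter is applied to each foot's indicator signal separately and
    the results are recombined.  Smoothing the combined {0, 1, 2}
    sequence directly would let a window that partially overlaps a
    right-foot plateau (w/2 samples of value 2) average to exactly 1,
    fabricating a left-foot peak next to every right-foot peak at every
    even window — the window-growing convergence loop could then never
    see two successive windows agree.  A binary indicator has no such
    failure mode: its moving mean is a whole number only at full overlap,
    so peaks shrink by w−1 samples, never split sides, and windows wider
    than a run simply delete it.

    Implemented in exact integer arithmetic (the mean over w labels is
    whole iff the window sum is divisible by w).  Edges are zero-padded,
    which only suppresses, never creates, peaks.  Even windows — required
    by the +1-per-iteration convergence loop — are centered with numpy's
    'same' convention (half-sample offset).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = labels.labels
    kernel = np.ones(window, dtype=np.int64)
    out = np.zeros(len(x), dtype=np.int64)
    for side in (1, 2):
        ind = (x == side).astype(np.int64)
        sums = np.convolve(ind, kernel, mode="same")
        out[(sums % window == 0) & (sums // window == 1)] = side
    return LabelSequence(labels=out, sample_rate_hz=labels.sample_rate_hz)


def count_peaks(labels: LabelSequence) -> tuple[int, np.ndarray]:
    """One peak per maximal constant nonzero run; side = the run's label.

    Adjacent runs of different nonzero values (1 touching 2 with no 0
    between) split at the value change.
    """
    x = labels.labels
    if len(x) == 0:
        return 0, np.array([], dtype=np.int64)
    starts = np.concatenate(([0], np.flatnonzero(np.diff(x) != 0) + 1))
    vals = x[starts]
    sides = vals[vals != 0]
    return len(sides), sides


def enforce_alternation(sides) -> tuple[int, int]:
    """Drop the later of two equal consecutive sides; return (kept, removed)."""
    kept = 0
    removed = 0
    last = None
    for s in np.asarray(sides).tolist():
        if s == last:
            removed += 1
        else:
            kept += 1
            last = s
    return kept, removed


def _corrected_count(quantized: LabelSequence, window: int) -> tuple[int, int]:
    n, sides = count_peaks(smooth(quantized, window))
    return enforce_alternation(sides)


def converged_count(
    trace: OpticalTrace,
    low_cut: float = DEFAULT_LOW_CUT_V,
    class_cut: float = DEFAULT_CLASS_CUT_V,
    band_split: float = DEFAULT_BAND_SPLIT_V,
    window_start: int = DEFAULT_WINDOW_START,
    window_cap: int = DEFAULT_WINDOW_CAP,
    trial: str | None = None,
) -> GroundTruthCount:
    """Grow the filter window until two successive corrected counts agree."""
    q = quantize(trace, low_cut=low_cut, class_cut=class_cut, band_split=band_split)
    w = window_start
    prev, prev_removed = _corrected_count(q, w)
    iterations = 0
    while w + 1 <= window_cap:
        cur, cur_removed = _corrected_count(q, w + 1)
        iterations += 1
        if cur == prev:
            return GroundTruthCount(steps=prev, window_used=w,
                                    iterations=iterations,
                                    repeats_removed=prev_removed)
        prev, prev_removed = cur, cur_removed
        w += 1
    raise ConvergenceError(
        f"ground-truth count did not converge within window cap {window_cap}"
        + (f" (trial {trial})" if trial else "")
    )


def compute_error(sensor_steps: int, true_steps: int) -> float:
    """Signed fractional error (sensor − truth)/truth; negative = missed steps."""
    if true_steps <= 0:
        raise ValueError("true step count must be positive")
    return (sensor_steps - true_steps) / true_steps


def _trial_seeds(run_seed: int, index: int) -> tuple[int, int, int]:
    """Derive (trial_seed, optical_seed, impulse_seed) for one trial.

    trial_seed = first word of SeedSequence([run_seed, index]); the two
    stream seeds derive from the trial seed alone, so a single recorded
    trial seed reproduces the trial.
    """
    trial_seed = int(np.random.SeedSequence([run_seed, index]).generate_state(1)[0]) % 2**31
    opt, imp = np.random.SeedSequence([trial_seed]).generate_state(2)
    return trial_seed, int(opt) % 2**31, int(imp) % 2**31


def sample_low_high_cadences(
    n: int, seed: int, low_band=(30, 70), high_band=(70, 111)
) -> list[tuple[int, int]]:
    """Per-setting (low, high) integer cadence pairs, seeded.

    Emulates the bench protocol of testing every setting combination at
    one low and one high walking speed, with the speeds spread over the
    full 30–110 steps/min range across the batch.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCAD]))
    lows = rng.integers(low_band[0], low_band[1], size=n)
    highs = rng.integers(high_band[0], high_band[1], size=n)
    return [(int(lo), int(hi)) for lo, hi in zip(lows, highs)]


def run_experiment(
    settings_list: list[SensorSettings],
    cadences,
    duration_s: float = 2700.0,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    sample_rate_hz: float = 100.0,
    window_cap: int = DEFAULT_WINDOW_CAP,
) -> pd.DataFrame:
    """Run the full bench and return the trial-record table.

    ``cadences`` is either a list of integer cadences (every setting is
    run at every listed cadence) or the string ``"low-high"`` (each
    setting is run at one seeded low and one seeded high cadence, the
    hardware bench protocol).  A failed trial is logged and skipped; it
    does not abort the batch.
    """
    if not settings_list:
        raise ValueError("settings_list must be non-empty")
    noise = CLEAN if noise is None else noise
    if isinstance(cadences, str):
        if cadences != "low-high":
            raise ValueError(f"unknown cadence mode {cadences!r}")
        pairs = sample_low_high_cadences(len(settings_list), seed)
        trials = [(s, c) for s, pair in zip(settings_list, pairs) for c in pair]
    else:
        cadences = list(cadences)
        if not cadences:
            raise ValueError("cadence list must be non-empty")
        trials = [(s, c) for s in settings_list for c in cadences]

    rows = []
    for i, (s, cadence) in enumerate(trials):
        trial_seed, opt_seed, imp_seed = _trial_seeds(seed, i)
        try:
            trace = generate_optical_trace(
                cadence, duration_s, noise=replace(noise, seed=opt_seed),
                sample_rate_hz=sample_rate_hz,
            )
            gt = converged_count(trace, window_cap=window_cap,
                                 trial=f"#{i} {s.as_tuple()} @ {cadence} spm")
            train = generate_impulse_train(
                cadence, duration_s, noise=replace(noise, seed=imp_seed))
            result = simulate_sensor(train, s)
            rows.append({
                "threshold_mg": s.threshold_mg,
                "debounce_steps": s.debounce_steps,
                "debounce_time_ms": s.debounce_time_ms,
                "cadence_spm": cadence,
                "true_steps": gt.steps,
                "sensor_steps": result.steps,
                "error_frac": compute_error(result.steps, gt.steps),
                "seed": trial_seed,
            })
        except Exception as exc:  # noqa: BLE001 — per-trial isolation
            log.warning("trial %d (%s @ %s spm) failed: %s",
                        i, s.as_tuple(), cadence, exc)
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
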