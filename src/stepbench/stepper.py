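"""Seeded software stand-in for the mechanical continuous stepper.

The physical rig is a motor-driven cam that alternately lifts and drops
two 2.5 kg pistons ("left" and "right" feet) onto foam, producing a
~1.1 g impact per step, while an optical distance sensor watching the cam
fins emits a voltage peak per step (sampled at 100 Hz).  This module
replaces the rig with two generators that share a step clock:

* :func:`generate_optical_trace` — the distance-sensor voltage trace
  (alternating rectangular peaks at two amplitudes, one per foot), plus
  the true step log; optional single-sample voltage spikes emulate the
  optical glitches the ground-truth pipeline must reject.
* :func:`generate_impulse_train` — the acceleration impulse train the
  wearable sensor sees (one ~1.1 g peak per foot impact), with optional
  Gaussian timing/amplitude jitter.

Convention: the first step lands at t = 60/cadence s (no event at t = 0),
so a noise-free trial of ``duration`` seconds contains exactly
``floor(duration * cadence / 60)`` steps.

Everything is deterministic given the :class:`NoiseSpec` seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .settings import _check_cadence

log = logging.getLogger(__name__)

DEFAULT_SAMPLE_RATE_HZ = 100.0
DEFAULT_PEAK_G = 1.1          # foot-impact magnitude of the rig (15 N pistons)
DEFAULT_LEFT_PEAK_V = 1.5
DEFAULT_RIGHT_PEAK_V = 2.5
# Dwell of a fin in front of the distance sensor: 7 samples (70 ms at
# 100 Hz).  Peaks must be wider than the largest moving-mean window the
# ground-truth loop typically needs, and narrower than the shortest
# inter-step interval (545 ms at 110 steps/min).
DEFAULT_PEAK_WIDTH_SAMPLES = 7


@dataclass(frozen=True)
class NoiseSpec:
    """Noise/imperfection parameters for the simulated rig.

    ``spike_rate_per_min``/``spike_amplitude_v`` parameterize Poisson-placed
    single-sample voltage glitches on the optical trace;
    ``timing_jitter_sd_s``/``amplitude_jitter_sd_g`` are Gaussian jitters on
    impulse-train event times and peaks.  All zero → a perfectly clean rig.
    """

    spike_rate_per_min: float = 0.0
    spike_amplitude_v: float = 3.0
    timing_jitter_sd_s: float = 0.0
    amplitude_jitter_sd_g: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spike_rate_per_min", "spike_amplitude_v",
                     "timing_jitter_sd_s", "amplitude_jitter_sd_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: Default simulated study conditions: a DC-motor cam holds cadence to
#: roughly 1–2% (20 ms timing sd on ~1 s gaps), foam impacts vary by ~5%
#: in peak g, and the optical sensor produces a few single-sample glitches
#: per minute well above the quantization threshold.
DEFAULT_NOISE = NoiseSpec(
    spike_rate_per_min=2.0,
    spike_amplitude_v=3.0,
    timing_jitter_sd_s=0.02,
    amplitude_jitter_sd_g=0.05,
    seed=0,
)

CLEAN = NoiseSpec()


@dataclass(frozen=True)
class OpticalTrace:
    """Sampled distance-sensor voltages plus the true step log."""

    sample_rate_hz: float
    voltages: np.ndarray
    true_steps: tuple[tuple[float, str], ...]  # (time s, "left"|"right")

    @property
    def true_count(self) -> int:
        return len(self.true_steps)

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(len(self.voltages)) / self.sample_rate_hz
        return pd.DataFrame({"time_s": t, "volts": self.voltages})


@dataclass(frozen=True)
class ImpulseTrain:
    """Timestamped acceleration peaks fed to the pedometer state machine."""

    times_s: np.ndarray
    peaks_g: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times_s) < 0):
            raise ValueError("impulse times must be sorted")
        if np.any(self.peaks_g < 0):
            raise ValueError("impulse peaks must be non-negative")

    @property
    def events(self) -> list[tuple[float, float]]:
        return list(zip(self.times_s.tolist(), self.peaks_g.tolist()))

    def __len__(self) -> int:
        return len(self.times_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times_s, "peak_g": self.peaks_g})


def _step_times(cadence: float, duration_s: float) -> np.ndarray:
    """Nominal step times: k * 60/cadence for k = 1..floor(duration*cadence/60)."""
    interval = 60.0 / cadence
    n = int(np.floor(duration_s * cadence / 60.0 + 1e-9))
    return np.arange(1, n + 1) * interval


def generate_optical_trace(
    cadence: float,
    duration_s: float,
    noise: NoiseSpec | None = None,
    left_peak_v: float = DEFAULT_LEFT_PEAK_V,
    right_peak_v: float = DEFAULT_RIGHT_PEAK_V,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    peak_width_samples: int = DEFAULT_PEAK_WIDTH_SAMPLES,
) -> OpticalTrace:
    """Simulate the distance-sensor voltage trace for one trial.

    Rectangular peaks of ``peak_width_samples`` samples alternate
    left/right (starting left) at the inter-step interval 60/cadence s
    over a 0 V baseline.  Each peak occupies the ``peak_width_samples``
    samples immediately before its step sample (the fin sweeps past the
    sensor just ahead of impact), so the final step of a trial — which
    lands exactly at t = duration — is still fully represented in the
    trace.  Poisson-placed single-sample spikes of
    ``noise.spike_amplitude_v`` are overlaid at ``noise.spike_rate_per_min``
    on baseline samples only — the sensor reads the nearby fin during a
    peak, so glitches occur while it stares at the far background.
    """
    _check_cadence(cadence)
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    interval = 60.0 / cadence
    if peak_width_samples / sample_rate_hz >= interval:
        raise ValueError(
            f"peak width {peak_width_samples} samples at {sample_rate_hz:g} Hz "
            f"is not shorter than the inter-step interval {interval:g} s; "
            "peaks would merge"
        )
    noise = CLEAN if noise is None else noise
    n_samples = int(round(duration_s * sample_rate_hz))
    v = np.zeros(n_samples)
    times = _step_times(cadence, duration_s)
    sides = ["left" if k % 2 == 0 else "right" for k in range(len(times))]
    for t, side in zip(times, sides):
        end = int(round(t * sample_rate_hz))      # peak culminates at impact
        lo = max(end - peak_width_samples, 0)
        hi = min(end, n_samples)
        v[lo:hi] = left_peak_v if side == "left" else right_peak_v
    if noise.spike_rate_per_min > 0:
        rng = np.random.default_rng(noise.seed)
        n_spikes = rng.poisson(noise.spike_rate_per_min * duration_s / 60.0)
        baseline = np.flatnonzero(v == 0.0)
        if n_spikes > 0 and len(baseline) > 0:
            pos = rng.choice(baseline, size=n_spikes)
            v[pos] = noise.spike_amplitude_v
    return OpticalTrace(
        sample_rate_hz=sample_rate_hz,
        voltages=v,
        true_steps=tuple(zip(times.tolist(), sides)),
    )


def generate_impulse_train(
    cadence: float,
    duration_s: float,
    peak_g: float = DEFAULT_PEAK_G,
    noise: NoiseSpec | None = None,
) -> ImpulseTrain:
    """Simulate the foot-impact acceleration train for one trial."""
    _check_cadence(cadence)
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    noise = CLEAN if noise is None else noise
    times = _step_times(cadence, duration_s)
    peaks = np.full(len(times), float(peak_g))
    if noise.timing_jitter_sd_s > 0 or noise.amplitude_jitter_sd_g > 0:
        rng = np.random.default_rng(noise.seed + 1)  # decorrelate from spike stream
        if noise.timing_jitter_sd_s > 0:
            times = times + rng.normal(0.0, noise.timing_jitter_sd_s, len(times))
            times = np.sort(np.clip(times, 0.0, None))
        if noise.amplitude_jitter_sd_g > 0:
            peaks = peaks + rng.normal(0.0, noise.amplitude_jitter_sd_g, len(peaks))
            n_clipped = int(np.sum(peaks < 0))
            if n_clipped:
                log.warning("clipped %d negative impulse peaks to 0", n_clipped)
                peaks = np.clip(peaks, 0.0, None)
    return ImpulseTrain(times_s=times, peaks_g=peaks, duration_s=float(duration_s))
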