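"""Deterministic state machine emulating the embedded pedometer.

The device counts steps from acceleration impulses under three settings:
a peak **threshold** (mg), a **debounce step** count, and a **debounce
time** window (ms).  Semantics:

* Only impulses with peak >= threshold are candidates.
* DEBOUNCING: consecutive candidates each arriving within the debounce
  window of the previous one accumulate; once ``debounce_steps`` have
  accumulated the bout is promoted to COUNTING and the accumulated
  impulses are credited retroactively (a fully connected bout of 12
  impulses yields 12 steps).  A longer gap while debouncing discards the
  accumulated impulses.
* COUNTING: each impulse within the window of the previous one adds one
  step; a longer gap closes the bout and the machine returns to
  DEBOUNCING.

Gap comparison is inclusive: a gap exactly equal to the debounce time
passes, so a 2000 ms window fully captures a metronomic 30 steps/min
train (2 s gaps).

A bout is a *grouping* of impulses: promotion always requires at least
two impulses connected by a qualifying gap, even at ``debounce_steps=1``
(otherwise every isolated jolt would count as a one-step bout and the
debounce window would gate nothing).  Consequently a regular train whose
gap exceeds the window yields zero steps at every setting — e.g. nothing
below 60 steps/min is detected with a 1000 ms window.

Whether real hardware credits the debounced impulses retroactively is not
documented; ``retroactive=False`` gives the alternative reading (only the
promoting impulse is credited, earlier accumulated impulses are dropped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .settings import SensorSettings
from .stepper import ImpulseTrain

#: Slack on the inclusive gap comparison, to keep exact-boundary gaps
#: (e.g. 2.0 s from a 30 steps/min train vs a 2000 ms window) inclusive
#: under floating-point round-off.
_GAP_EPS_S = 1e-9


@dataclass(frozen=True)
class PedometerResult:
    """Outcome of running the state machine over one impulse list."""

    steps: int
    discarded_impulses: int
    bouts: tuple[tuple[float, float, int], ...]  # (start s, end s, steps)

    def __post_init__(self) -> None:
        assert self.steps == sum(b[2] for b in self.bouts)


def detect_impulses(train: ImpulseTrain, threshold_mg: float) -> np.ndarray:
    """Times of impulses whose peak reaches the threshold (peak >= threshold)."""
    mask = train.peaks_g * 1000.0 >= threshold_mg
    return train.times_s[mask]


def count_steps(
    impulse_times,
    settings: SensorSettings,
    retroactive: bool = True,
) -> PedometerResult:
    """Run the debounce/counting state machine over sorted impulse times."""
    times = np.asarray(impulse_times, dtype=float)
    if times.ndim != 1:
        raise ValueError("impulse times must be a 1-D sequence")
    if np.any(np.diff(times) < 0):
        raise ValueError("impulse times must be sorted ascending")
    window = settings.debounce_time_ms / 1000.0 + _GAP_EPS_S
    need = max(settings.debounce_steps, 2)   # a bout is at least two connected impulses

    steps_total = 0
    discarded = 0
    bouts: list[tuple[float, float, int]] = []
    pending: list[float] = []          # DEBOUNCING accumulator
    bout: list | None = None           # [start, last, count] while COUNTING
    prev: float | None = None

    for t in times:
        connected = prev is None or (t - prev) <= window
        if bout is not None:           # COUNTING
            if connected:
                bout[1] = t
                bout[2] += 1
            else:                      # collection ceases; restart debouncing
                bouts.append((bout[0], bout[1], bout[2]))
                steps_total += bout[2]
                bout = None
                pending = [t]
        else:                          # DEBOUNCING
            if connected:
                pending.append(t)
            else:                      # accumulated impulses are discarded
                discarded += len(pending)
                pending = [t]
        if bout is None and len(pending) >= need:
            if retroactive:
                bout = [pending[0], t, len(pending)]
            else:
                discarded += len(pending) - 1
                bout = [t, t, 1]
            pending = []
        prev = t

    if bout is not None:
        bouts.append((bout[0], bout[1], bout[2]))
        steps_total += bout[2]
    else:
        discarded += len(pending)
    return PedometerResult(steps=steps_total, discarded_impulses=discarded,
                           bouts=tuple(bouts))


def simulate_sensor(
    train: ImpulseTrain,
    settings: SensorSettings,
    retroactive: bool = True,
) -> PedometerResult:
    """Threshold detection followed by the counting state machine."""
    return count_steps(detect_impulses(train, settings.threshold_mg),
                       settings, retroactive=retroactive)


def min_detectable_cadence(debounce_time_ms: float) -> int:
    """Smallest integer cadence whose regular inter-step gap fits the window.

    A regular train at cadence c has gaps of 60000/c ms; under the
    inclusive comparison the train is detected iff 60000/c <= debounce
    time, i.e. c >= ceil(60000/debounce_time).  E.g. a 1000 ms window
    detects nothing below 60 steps/min.
    """
    if debounce_time_ms <= 0:
        raise ValueError("debounce time must be positive")
    return math.ceil(60000.0 / debounce_time_ms - 1e-9)
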