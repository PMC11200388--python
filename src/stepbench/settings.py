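"""Sensor-setting space for an LSM6DSL-style embedded pedometer.

Low-power step-count sensors expose three configuration knobs:

* **threshold** — minimum acceleration peak, in milli-g, an impulse must
  reach to be a candidate step (the device's ``CONFIG_PEDO_THS_MIN``
  register): 35 options spanning 32–996 mg;
* **debounce steps** — consecutive qualifying impulses required before a
  bout of impulses is accepted as walking: 1–7;
* **debounce time** — maximum gap after an impulse within which the next
  impulse must arrive: 80–2480 ms in 80 ms increments (31 options).

The Cartesian product gives 7595 setting combinations.  This module
enumerates, subsamples, and min–max normalizes that space (plus the
30–110 steps/min cadence axis) for downstream regression modelling.

The hardware register spacing of the threshold axis is not public; the
grid here is 35 uniformly spaced values from 32 to 996 mg, kept as an
explicit module-level tuple so a hardware-faithful grid can be swapped in.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# Setting grids.  Threshold spacing (996-32)/34 ≈ 28.35 mg.
THRESHOLD_MG_GRID: tuple[float, ...] = tuple(float(v) for v in np.linspace(32.0, 996.0, 35))
DEBOUNCE_STEPS_GRID: tuple[int, ...] = tuple(range(1, 8))
DEBOUNCE_TIME_MS_GRID: tuple[float, ...] = tuple(float(t) for t in range(80, 2481, 80))

CADENCE_MIN: float = 30.0
CADENCE_MAX: float = 110.0

#: Min–max bounds used for normalization, in the fixed component order
#: (threshold_mg, debounce_time_ms, debounce_steps, cadence_spm).  Bounds
#: are the grid extremes, not observed-data extremes, so the model is
#: evaluated on [0, 1]^4 over the whole space.
NORMALIZATION_BOUNDS: tuple[tuple[float, float], ...] = (
    (32.0, 996.0),
    (80.0, 2480.0),
    (1.0, 7.0),
    (CADENCE_MIN, CADENCE_MAX),
)

#: Names of the normalized components, in order.
COMPONENT_NAMES = ("threshold_mg", "debounce_time_ms", "debounce_steps", "cadence_spm")


@dataclass(frozen=True, order=True)
class SensorSettings:
    """One point in the (threshold, debounce steps, debounce time) space."""

    threshold_mg: float
    debounce_steps: int
    debounce_time_ms: float

    def as_tuple(self) -> tuple[float, int, float]:
        return (self.threshold_mg, self.debounce_steps, self.debounce_time_ms)


@dataclass(frozen=True)
class CadenceRange:
    """Closed integer cadence range [low, high] in steps/min, with a label."""

    low: int
    high: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (CADENCE_MIN <= self.low < self.high <= CADENCE_MAX):
            raise ValueError(
                f"cadence range must satisfy {CADENCE_MIN:g} <= low < high <= "
                f"{CADENCE_MAX:g}, got [{self.low}, {self.high}]"
            )

    def cadences(self) -> np.ndarray:
        """Every integer cadence in the range, inclusive."""
        return np.arange(self.low, self.high + 1)


def enumerate_settings() -> list[SensorSettings]:
    """The full 35 × 7 × 31 = 7595 grid, in lexicographic order
    (threshold, then debounce steps, then debounce time)."""
    return [
        SensorSettings(thr, ds, dt)
        for thr, ds, dt in itertools.product(
            THRESHOLD_MG_GRID, DEBOUNCE_STEPS_GRID, DEBOUNCE_TIME_MS_GRID
        )
    ]


def subsample_settings(
    strides: tuple[int, int, int] = (2, 4, 5),
) -> list[SensorSettings]:
    """Subsample the grid by keeping indices 0, s, 2s, … along each axis.

    ``strides`` is ``(steps_stride, time_stride, threshold_stride)`` —
    the order in which the sampling intervals are conventionally quoted
    (steps every 2, debounce time every 4, threshold every 5 data points,
    giving 4 × 8 × 7 = 224 settings).  Output order matches
    :func:`enumerate_settings`.
    """
    steps_stride, time_stride, thr_stride = strides
    axes = (
        ("debounce_steps", steps_stride, len(DEBOUNCE_STEPS_GRID)),
        ("debounce_time", time_stride, len(DEBOUNCE_TIME_MS_GRID)),
        ("threshold", thr_stride, len(THRESHOLD_MG_GRID)),
    )
    for name, stride, length in axes:
        if not (isinstance(stride, (int, np.integer)) and stride > 0):
            raise ValueError(f"{name} stride must be a positive integer, got {stride!r}")
        if stride >= length:
            log.warning(
                "%s stride %d >= axis length %d; only the first grid value is retained",
                name, stride, length,
            )
    thr = THRESHOLD_MG_GRID[::thr_stride]
    steps = DEBOUNCE_STEPS_GRID[::steps_stride]
    times = DEBOUNCE_TIME_MS_GRID[::time_stride]
    return [
        SensorSettings(t, s, d) for t, s, d in itertools.product(thr, steps, times)
    ]


def _check_cadence(cadence: float) -> None:
    if not (CADENCE_MIN <= cadence <= CADENCE_MAX):
        raise ValueError(
            f"cadence {cadence} steps/min outside supported range "
            f"[{CADENCE_MIN:g}, {CADENCE_MAX:g}]"
        )


def normalize(settings: SensorSettings, cadence: float) -> np.ndarray:
    """Min–max scale one (settings, cadence) point to [0, 1]^4.

    Component order is (threshold, debounce time, debounce steps, cadence);
    see :data:`NORMALIZATION_BOUNDS`.
    """
    _check_cadence(cadence)
    return normalize_array(
        np.array([settings.threshold_mg]),
        np.array([settings.debounce_time_ms]),
        np.array([settings.debounce_steps], dtype=float),
        np.array([cadence]),
    )[0]


def normalize_array(
    threshold_mg: np.ndarray,
    debounce_time_ms: np.ndarray,
    debounce_steps: np.ndarray,
    cadence_spm: np.ndarray,
) -> np.ndarray:
    """Vectorized :func:`normalize`; returns an (n, 4) array."""
    cadence_spm = np.asarray(cadence_spm, dtype=float)
    if np.any(cadence_spm < CADENCE_MIN) or np.any(cadence_spm > CADENCE_MAX):
        raise ValueError("cadence outside supported range [30, 110] steps/min")
    cols = []
    for raw, (lo, hi) in zip(
        (threshold_mg, debounce_time_ms, debounce_steps, cadence_spm),
        NORMALIZATION_BOUNDS,
    ):
        cols.append((np.asarray(raw, dtype=float) - lo) / (hi - lo))
    return np.column_stack(cols)


def denormalize(x: np.ndarray) -> tuple[SensorSettings, float]:
    """Inverse of :func:`normalize` for a single 4-vector."""
    x = np.asarray(x, dtype=float)
    raw = [lo + xi * (hi - lo) for xi, (lo, hi) in zip(x, NORMALIZATION_BOUNDS)]
    thr, dt, ds, cadence = raw
    return SensorSettings(thr, int(round(ds)), dt), cadence


def settings_to_frame(settings_list: list[SensorSettings]) -> pd.DataFrame:
    """Settings table with the CSV-contract columns."""
    return pd.DataFrame(
        {
            "threshold_mg": [s.threshold_mg for s in settings_list],
            "debounce_steps": [s.debounce_steps for s in settings_list],
            "debounce_time_ms": [s.debounce_time_ms for s in settings_list],
        }
    )


def frame_to_settings(frame: pd.DataFrame) -> list[SensorSettings]:
    return [
        SensorSettings(float(r.threshold_mg), int(r.debounce_steps), float(r.debounce_time_ms))
        for r in frame.itertuples()
    ]


def grid_config() -> dict:
    """The setting grids as a plain dict (YAML/JSON-serializable)."""
    return {
        "threshold_mg": list(THRESHOLD_MG_GRID),
        "debounce_steps": list(DEBOUNCE_STEPS_GRID),
        "debounce_time_ms": list(DEBOUNCE_TIME_MS_GRID),
        "cadence_spm": [CADENCE_MIN, CADENCE_MAX],
    }
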