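"""Setting recommendation over a cadence range.

For every setting combination, predicted signed errors are evaluated at
every integer cadence in a range of interest, then summarized as

* AE  — mean magnitude of predicted error (a signed-mean mode exists for
  literal comparison with the composite equation as sometimes printed;
  the magnitude is the default because the goal is minimizing the size
  of the error, and a signed mean would reward large undercounts),
* STD — sample standard deviation of the signed errors across cadences,
* composite = w·AE + (1−w)·STD  (w in [0, 1], default 0.5),
* within tolerance ⇔ |predicted error| <= 0.10 at every integer cadence
  (the strictest pointwise reading of "consistently within ±10%").

Recommendation filters to within-tolerance settings and ranks ascending
by composite, ties broken by (std, ae, threshold, debounce time,
debounce steps).  The three preset ranges of interest are 30–60
(disabled low-mobility ambulators), 30–90 (disabled high-mobility
ambulators) and 30–110 steps/min (healthy individuals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .error_model import ErrorModel
from .settings import CadenceRange, SensorSettings, enumerate_settings, normalize_array

log = logging.getLogger(__name__)

DEFAULT_W = 0.5
DEFAULT_TOLERANCE = 0.10
_TOL_EPS = 1e-12


@dataclass(frozen=True)
class SettingEvaluation:
    settings: SensorSettings
    ae: float
    std: float
    composite: float
    within_tolerance: bool


@dataclass(frozen=True)
class RecommendationResult:
    cadence_range: CadenceRange
    w: float
    tolerance: float
    evaluations: tuple[SettingEvaluation, ...]          # within tolerance, ranked
    fallback: tuple[SettingEvaluation, ...] = ()        # best out-of-tolerance, if empty

    @property
    def empty(self) -> bool:
        return not self.evaluations


def preset_ranges() -> list[CadenceRange]:
    """The three cadence ranges of interest."""
    return [
        CadenceRange(30, 60, "disabled low-mobility"),
        CadenceRange(30, 90, "disabled high-mobility"),
        CadenceRange(30, 110, "healthy"),
    ]


def _summaries(pred: np.ndarray, w: float, tolerance: float, signed_ae: bool):
    """AE/STD/composite/tolerance flags for a (n_settings, n_cadences) block."""
    ae = pred.mean(axis=1) if signed_ae else np.abs(pred).mean(axis=1)
    std = pred.std(axis=1, ddof=1)
    composite = w * ae + (1.0 - w) * std
    within = np.all(np.abs(pred) <= tolerance + _TOL_EPS, axis=1)
    return ae, std, composite, within


def evaluate_setting(
    model: ErrorModel,
    settings: SensorSettings,
    cadence_range: CadenceRange,
    w: float = DEFAULT_W,
    tolerance: float = DEFAULT_TOLERANCE,
    signed_ae: bool = False,
) -> SettingEvaluation:
    """Evaluate one setting combination over every integer cadence in range."""
    if not (0.0 <= w <= 1.0):
        raise ValueError("w must lie in [0, 1]")
    cads = cadence_range.cadences().astype(float)
    n = len(cads)
    Xn = normalize_array(
        np.full(n, settings.threshold_mg),
        np.full(n, settings.debounce_time_ms),
        np.full(n, float(settings.debounce_steps)),
        cads,
    )
    pred = model.predict_normalized(Xn)[None, :]
    ae, std, composite, within = _summaries(pred, w, tolerance, signed_ae)
    return SettingEvaluation(settings, float(ae[0]), float(std[0]),
                             float(composite[0]), bool(within[0]))


def _rank(evals: list[SettingEvaluation]) -> list[SettingEvaluation]:
    return sorted(
        evals,
        key=lambda e: (e.composite, e.std, e.ae, e.settings.threshold_mg,
                       e.settings.debounce_time_ms, e.settings.debounce_steps),
    )


def recommend(
    model: ErrorModel,
    cadence_range: CadenceRange,
    w: float = DEFAULT_W,
    tolerance: float = DEFAULT_TOLERANCE,
    top_n: int = 10,
    settings_list: list[SensorSettings] | None = None,
    signed_ae: bool = False,
) -> RecommendationResult:
    """Rank all setting combinations for a cadence range.

    Evaluates every setting (the full 7595-point grid by default) at
    every integer cadence in the range, filters to within-tolerance
    candidates, and returns the ``top_n`` by composite score.  When no
    setting is within tolerance, the result is empty and carries the
    best out-of-tolerance candidates as a structured fallback (also
    logged as a warning).
    """
    if not (0.0 <= w <= 1.0):
        raise ValueError("w must lie in [0, 1]")
    if settings_list is None:
        settings_list = enumerate_settings()
    cads = cadence_range.cadences().astype(float)
    thr = np.array([s.threshold_mg for s in settings_list])
    ds = np.array([float(s.debounce_steps) for s in settings_list])
    dt = np.array([s.debounce_time_ms for s in settings_list])
    # Predict cadence-by-cadence to keep the design matrix small.
    pred = np.empty((len(settings_list), len(cads)))
    for j, c in enumerate(cads):
        Xn = normalize_array(thr, dt, ds, np.full(len(settings_list), c))
        pred[:, j] = model.predict_normalized(Xn)
    ae, std, composite, within = _summaries(pred, w, tolerance, signed_ae)
    evals = [
        SettingEvaluation(s, float(a), float(sd), float(co), bool(wi))
        for s, a, sd, co, wi in zip(settings_list, ae, std, composite, within)
    ]
    in_tol = _rank([e for e in evals if e.within_tolerance])
    if in_tol:
        return RecommendationResult(cadence_range, w, tolerance,
                                    tuple(in_tol[:top_n]))
    fallback = _rank(evals)[:top_n]
    log.warning(
        "no setting within ±%.0f%% over %s; best out-of-tolerance candidates: %s",
        tolerance * 100, cadence_range,
        [(f.settings.as_tuple(), round(f.composite, 4)) for f in fallback[:5]],
    )
    return RecommendationResult(cadence_range, w, tolerance, (), tuple(fallback))


def recommendations_to_frame(result: RecommendationResult) -> pd.DataFrame:
    """Recommendation report as a table (one row per ranked candidate)."""
    evals = result.evaluations or result.fallback
    return pd.DataFrame({
        "rank": np.arange(1, len(evals) + 1),
        "threshold_mg": [e.settings.threshold_mg for e in evals],
        "debounce_steps": [e.settings.debounce_steps for e in evals],
        "debounce_time_ms": [e.settings.debounce_time_ms for e in evals],
        "ae": [e.ae for e in evals],
        "std": [e.std for e in evals],
        "composite": [e.composite for e in evals],
        "within_tolerance": [e.within_tolerance for e in evals],
        "range_low": result.cadence_range.low,
        "range_high": result.cadence_range.high,
        "range_label": result.cadence_range.label,
        "w": result.w,
    })
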