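"""Multivariate polynomial regression (MPR) of sensor error.

Signed step-count error is modelled as a polynomial in the four
normalized predictors (threshold, debounce time, debounce steps,
cadence), using the complete monomial basis of total degree <= d over
[0, 1]^4.  Orders 1–5 are compared on:

* R² and in-sample RMSE (fractional error units),
* CVMAE — k-fold cross-validated mean absolute error (also reported
  ×100 as ``cvmae_pct`` for comparability with percent-unit reports),
* Fit gap — test RMSE minus train RMSE under a seeded 90/10 split;
  positive suggests overfitting, negative underfitting.

Order selection takes the highest-R² degree whose design is not rank
deficient and whose fit gap does not exceed an overfit bound (default
0.05); R² ties break to the lowest degree.

Fitting is ordinary least squares via a rank-revealing SVD solver; a
design with numerical rank below its column count (or with fewer rows
than columns) is flagged as rank deficient and excluded from selection,
never silently tolerated.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .settings import CADENCE_MAX, CADENCE_MIN, COMPONENT_NAMES, NORMALIZATION_BOUNDS, SensorSettings, normalize

log = logging.getLogger(__name__)

N_VARS = 4
DEFAULT_DEGREES = (1, 2, 3, 4, 5)
DEFAULT_CV_FOLDS = 10
DEFAULT_OVERFIT_BOUND = 0.05
_R2_TIE_TOL = 1e-9


def monomial_exponents(degree: int, n_vars: int = N_VARS) -> np.ndarray:
    """Exponent tuples of all monomials with total degree <= degree.

    Graded order (total degree ascending), lexicographic within a grade;
    the first row is the intercept.  Row count is C(degree + n_vars, n_vars).
    """
    if degree < 0:
        raise ValueError("degree must be non-negative")
    rows = []
    for total in range(degree + 1):
        for combo in itertools.combinations_with_replacement(range(n_vars), total):
            e = [0] * n_vars
            for v in combo:
                e[v] += 1
            rows.append(e)
    return np.array(rows, dtype=np.int64)


def design_matrix(X: np.ndarray, degree: int) -> np.ndarray:
    """Monomial feature matrix for normalized predictors X (n × 4)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != N_VARS:
        raise ValueError(f"X must have {N_VARS} columns")
    exps = monomial_exponents(degree)
    # (n, m): product over variables of x_v ** e_{mv}
    return np.prod(X[:, None, :] ** exps[None, :, :], axis=2)


@dataclass
class ErrorModel:
    """Fitted polynomial error surface plus diagnostics."""

    degree: int
    exponents: np.ndarray
    coefficients: np.ndarray
    r_squared: float
    rmse: float
    rank: int
    rank_deficient: bool
    n_obs: int
    cvmae: float | None = None
    fit_gap: float | None = None
    bounds: tuple = NORMALIZATION_BOUNDS

    def predict_normalized(self, Xn: np.ndarray) -> np.ndarray:
        """Evaluate the polynomial at already-normalized points."""
        Xn = np.atleast_2d(np.asarray(Xn, dtype=float))
        return np.prod(Xn[:, None, :] ** self.exponents[None, :, :], axis=2) @ self.coefficients

    def predict(self, settings: SensorSettings, cadence: float) -> float:
        """Predicted signed error at one (settings, cadence) point.

        Cadence must lie in [30, 110]; the model never extrapolates
        outside the fitted cadence axis.
        """
        if not (CADENCE_MIN <= cadence <= CADENCE_MAX):
            raise ValueError("cadence outside [30, 110]: no extrapolation")
        return float(self.predict_normalized(normalize(settings, cadence)[None, :])[0])

    def to_json(self) -> str:
        return json.dumps({
            "degree": self.degree,
            "exponents": self.exponents.tolist(),
            "coefficients": self.coefficients.tolist(),
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "rank": self.rank,
            "rank_deficient": self.rank_deficient,
            "n_obs": self.n_obs,
            "cvmae": self.cvmae,
            "fit_gap": self.fit_gap,
            "normalization": {
                "components": list(COMPONENT_NAMES),
                "bounds": [list(b) for b in self.bounds],
            },
        })

    @classmethod
    def from_json(cls, text: str) -> "ErrorModel":
        d = json.loads(text)
        return cls(
            degree=d["degree"],
            exponents=np.array(d["exponents"], dtype=np.int64),
            coefficients=np.array(d["coefficients"], dtype=float),
            r_squared=d["r_squared"],
            rmse=d["rmse"],
            rank=d["rank"],
            rank_deficient=d["rank_deficient"],
            n_obs=d["n_obs"],
            cvmae=d.get("cvmae"),
            fit_gap=d.get("fit_gap"),
            bounds=tuple(tuple(b) for b in d["normalization"]["bounds"]),
        )


def _ols(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    return coef, int(rank)


def fit(X: np.ndarray, y: np.ndarray, degree: int) -> ErrorModel:
    """Least-squares MPR fit of y on the degree-d monomial basis of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    A = design_matrix(X, degree)
    n, m = A.shape
    coef, rank = _ols(A, y)
    rank_deficient = rank < m or n <= m
    if rank_deficient:
        log.warning("degree-%d fit is rank deficient (n=%d, m=%d, rank=%d)",
                    degree, n, m, rank)
    resid = y - A @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-24 else 0.0)
    return ErrorModel(
        degree=degree,
        exponents=monomial_exponents(degree),
        coefficients=coef,
        r_squared=r2,
        rmse=float(np.sqrt(rss / n)),
        rank=rank,
        rank_deficient=rank_deficient,
        n_obs=n,
    )


def cv_mae(X: np.ndarray, y: np.ndarray, degree: int,
           k: int = DEFAULT_CV_FOLDS, seed: int = 0) -> float:
    """k-fold cross-validated mean absolute error, pooled over held-out folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    A = design_matrix(X, degree)
    m = A.shape[1]
    abs_errors = []
    for train_idx, test_idx in KFold(n_splits=k, shuffle=True, random_state=seed).split(A):
        if len(train_idx) <= m:
            log.warning("CV fold train size %d <= %d features (degree %d); "
                        "CVMAE flagged as NaN", len(train_idx), m, degree)
            return float("nan")
        coef, _ = _ols(A[train_idx], y[train_idx])
        abs_errors.append(np.abs(y[test_idx] - A[test_idx] @ coef))
    return float(np.mean(np.concatenate(abs_errors)))


def fit_gap(X: np.ndarray, y: np.ndarray, degree: int,
            split: float = 0.9, seed: int = 0) -> float:
    """Test RMSE minus train RMSE under a seeded random train/test split."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = len(y)
    n_train = int(round(split * n))
    if n_train < 1 or n - n_train < 1:
        raise ValueError(f"degenerate {split:.0%} split for n={n}")
    A = design_matrix(X, degree)
    perm = np.random.default_rng(seed).permutation(n)
    tr, te = perm[:n_train], perm[n_train:]
    coef, _ = _ols(A[tr], y[tr])
    rmse_train = float(np.sqrt(np.mean((y[tr] - A[tr] @ coef) ** 2)))
    rmse_test = float(np.sqrt(np.mean((y[te] - A[te] @ coef) ** 2)))
    return rmse_test - rmse_train


def select_order(
    X: np.ndarray,
    y: np.ndarray,
    degrees=DEFAULT_DEGREES,
    k: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
    overfit_bound: float = DEFAULT_OVERFIT_BOUND,
) -> tuple[int, pd.DataFrame]:
    """Compare MPR orders and pick one.

    Returns the chosen degree and a diagnostics table (one row per
    degree: r_squared, rmse, cvmae, cvmae_pct, fit_gap, rank_deficient).
    Chosen: highest R² among degrees that are not rank deficient and
    whose fit gap is <= ``overfit_bound``; ties to the lowest degree.
    """
    rows = []
    models: dict[int, ErrorModel] = {}
    for d in degrees:
        model = fit(X, y, d)
        models[d] = model
        if model.rank_deficient:
            cvm, gap = float("nan"), float("nan")
        else:
            cvm = cv_mae(X, y, d, k=k, seed=seed)
            gap = fit_gap(X, y, d, seed=seed)
        model.cvmae = cvm
        model.fit_gap = gap
        rows.append({
            "degree": d,
            "n_terms": len(model.coefficients),
            "r_squared": model.r_squared,
            "rmse": model.rmse,
            "cvmae": cvm,
            "cvmae_pct": cvm * 100.0,
            "fit_gap": gap,
            "rank_deficient": model.rank_deficient,
        })
    table = pd.DataFrame(rows)
    eligible = table[
        ~table.rank_deficient & (table.fit_gap <= overfit_bound)
    ]
    if eligible.empty:
        if bool(table.rank_deficient.all()):
            raise ValueError("all tested degrees are rank deficient")
        raise ValueError(
            f"no degree satisfies the overfit bound {overfit_bound}; "
            "inspect the diagnostics table"
        )
    best_r2 = eligible.r_squared.max()
    chosen = int(eligible[eligible.r_squared >= best_r2 - _R2_TIE_TOL].degree.min())
    log.info("selected MPR order %d (R²=%.4f)", chosen, models[chosen].r_squared)
    return chosen, table
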