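"""PLS1 regression, leave-one-out cross-validation and the SECV / R_P,CV statistics.

Components are extracted by NIPALS on column-centered, unscaled data (the
single-response case needs no inner iteration).  All cross-validated searches
in this package go through :func:`loocv_predict_multi`, which extracts the
component sequence once per fold and reads off predictions for every factor
count, so scanning a factor grid costs one NIPALS run per fold, not one per
grid entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PLSModel",
    "PredictionRecord",
    "fit_pls",
    "predict",
    "loocv_predict",
    "loocv_predict_multi",
    "secv",
    "r_pcv",
    "select_factors",
]

# residual X norms below this are treated as exhausted; later factors are inert
_RESIDUAL_TOL = 1e-12


@dataclass(frozen=True)
class PLSModel:
    """A fitted PLS1 model: an affine map from absorbance rows to g/L."""

    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray
    training_wavelengths: tuple = ()

    def predict(self, X) -> np.ndarray:
        return predict(self, X)


@dataclass(frozen=True)
class PredictionRecord:
    """Measured values paired with cross-validated predictions."""

    measured: np.ndarray
    predicted: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.measured, dtype=float)
        p = np.asarray(self.predicted, dtype=float)
        if m.shape != p.shape or m.ndim != 1:
            raise ValueError("measured and predicted must be equal-length vectors")
        object.__setattr__(self, "measured", m)
        object.__setattr__(self, "predicted", p)

    @property
    def n_samples(self) -> int:
        return self.measured.size

    @property
    def measured_mean(self) -> float:
        return float(self.measured.mean())

    @property
    def predicted_mean(self) -> float:
        return float(self.predicted.mean())


def _nipals_coefs(Xc: np.ndarray, yc: np.ndarray, n_factors: int) -> np.ndarray:
    """Regression vectors for 1..n_factors components, shape (n_factors, N).

    Row a-1 is the coefficient vector of the a-component model on centered
    data.  Uses the recursion r_a = w_a - sum_j (p_j . w_a) r_j so each extra
    component costs O(a N).
    """
    X = Xc.copy()
    y = yc.copy()
    n, N = X.shape
    coefs = np.zeros((n_factors, N))
    R = np.zeros((n_factors, N))  # rotation vectors
    P = np.zeros((n_factors, N))
    b = np.zeros(N)
    for a in range(n_factors):
        w = X.T @ y
        wn = np.linalg.norm(w)
        if wn < _RESIDUAL_TOL:
            coefs[a:] = b
            return coefs
        w /= wn
        t = X @ w
        tt = float(t @ t)
        if tt < _RESIDUAL_TOL:
            coefs[a:] = b
            return coefs
        p = (X.T @ t) / tt
        q = float(y @ t) / tt
        r = w.copy()
        for j in range(a):
            r -= float(P[j] @ w) * R[j]
        R[a] = r
        P[a] = p
        b = b + q * r
        coefs[a] = b
        X -= np.outer(t, p)
        y -= q * t
    return coefs


def fit_pls(X, y, n_factors: int, wavelengths=()) -> PLSModel:
    """Fit a PLS1 model with ``n_factors`` latent components.

    X is column-centered and y centered; no variance scaling is applied.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-D matrix with at least one column")
    n, N = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match the number of rows of X")
    if not 1 <= n_factors <= min(n - 1, N):
        raise ValueError(
            f"n_factors={n_factors} outside feasible range 1..{min(n - 1, N)}"
        )
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance; nothing to regress on")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    coefs = _nipals_coefs(X - x_mean, y - y_mean, n_factors)
    return PLSModel(
        n_factors=n_factors,
        x_mean=x_mean,
        y_mean=y_mean,
        coef=coefs[n_factors - 1],
        training_wavelengths=tuple(wavelengths),
    )


def predict(model: PLSModel, X) -> np.ndarray:
    """Predict responses: centered X times the regression vector plus y_mean."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.coef.size:
        raise ValueError(
            f"X has {X.shape[1]} columns, model was trained on {model.coef.size}"
        )
    return (X - model.x_mean) @ model.coef + model.y_mean


def loocv_predict_multi(X, y, max_factors: int) -> np.ndarray:
    """Leave-one-out predictions for every factor count 1..max_factors.

    Returns an (n_samples, max_factors) matrix; column a-1 holds the LOOCV
    prediction of each sample by an (a)-component model trained on the other
    samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, N = X.shape
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    if not 1 <= max_factors <= min(n - 2, N):
        raise ValueError(
            f"max_factors={max_factors} infeasible for LOOCV with n={n}, N={N}"
        )
    out = np.empty((n, max_factors))
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        Xtr = X[keep]
        ytr = y[keep]
        if np.ptp(ytr) == 0:
            raise ValueError("a leave-one-out fold has zero-variance y")
        xm = Xtr.mean(axis=0)
        ym = ytr.mean()
        coefs = _nipals_coefs(Xtr - xm, ytr - ym, max_factors)
        out[i] = coefs @ (X[i] - xm) + ym
    return out


def loocv_predict(X, y, n_factors: int) -> PredictionRecord:
    """Leave-one-out cross-validated predictions at a single factor count."""
    preds = loocv_predict_multi(X, y, n_factors)
    return PredictionRecord(measured=np.asarray(y, dtype=float), predicted=preds[:, -1])


def secv(record: PredictionRecord) -> float:
    """Root-mean-square error of the cross-validated predictions."""
    d = record.predicted - record.measured
    return float(np.sqrt(np.mean(d * d)))


def r_pcv(record: PredictionRecord) -> float:
    """Correlation between measured and cross-validated predicted values."""
    m = record.measured - record.measured_mean
    p = record.predicted - record.predicted_mean
    denom = np.sqrt(float(m @ m) * float(p @ p))
    if denom == 0:
        raise ValueError(
            "correlation undefined: measured or predicted values are constant"
        )
    return float(m @ p / denom)


def select_factors(X, y, factor_grid):
    """Pick the factor count minimizing LOOCV SECV over ``factor_grid``.

    Infeasible grid entries are skipped; ties break toward the smaller
    factor count.  Returns ``(best_factors, record)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, N = X.shape
    grid = sorted({int(f) for f in factor_grid})
    if not grid:
        raise ValueError("factor grid is empty")
    bound = min(n - 2, N)
    feasible = [f for f in grid if 1 <= f <= bound]
    if not feasible:
        raise ValueError(
            f"no feasible factor count in grid (bound is {bound})"
        )
    preds = loocv_predict_multi(X, y, max(feasible))
    best_f = None
    best_secv = np.inf
    # SECV differences at machine-noise level are ties; ties keep the
    # smaller factor count (grid traversed ascending)
    tie_tol = 1e-9
    for f in feasible:
        d = preds[:, f - 1] - y
        s = float(np.sqrt(np.mean(d * d)))
        if best_f is None or s < best_secv - tie_tol * (1.0 + best_secv):
            best_secv = s
            best_f = f
    record = PredictionRecord(measured=y, predicted=preds[:, best_f - 1])
    return best_f, record
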