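"""Pairwise two-wavelength regression scoring and the best-partner mapping.

Every unordered wavelength pair (lambda_i, lambda_k) is scored by the LOOCV
root-mean-square error of the bivariate model

    y ~ b0 + b1 * x_i + b2 * x_k

computed with the closed-form leave-one-out identity
``press_i = residual_i / (1 - leverage_i)``, which makes a full-grid scan
(369,370 pairs on an 860-point grid) a desk-scale computation.  Pairs whose
design matrix is rank-deficient, or where any leverage reaches 1, receive an
+infinity sentinel and can never be selected as a best partner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nirsel.dataset import SpectraSet

__all__ = [
    "PairScoreMatrix",
    "PartnerMap",
    "blr_loocv_secv",
    "pairwise_scores",
    "best_partner_map",
]

_LEVERAGE_TOL = 1e-10
_DET_RTOL = 1e-12


@dataclass(frozen=True)
class PairScoreMatrix:
    """Symmetric matrix of pairwise LOOCV SECV scores.

    ``scores[i, k]`` is the score of the unordered pair (wavelengths[i],
    wavelengths[k]); the diagonal is NaN and non-identifiable pairs are
    +inf.
    """

    wavelengths: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (wl.size, wl.size):
            raise ValueError("score matrix shape must match wavelength count")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "scores", s)


@dataclass(frozen=True)
class PartnerMap:
    """The best-partner function f over a wavelength domain.

    ``partner[lam]`` is the wavelength minimizing the pair score with
    ``lam`` (never ``lam`` itself); ``score[lam]`` is that minimum.
    """

    wavelengths: np.ndarray
    partner_index: np.ndarray
    partner_score: np.ndarray = None

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        pi = np.asarray(self.partner_index, dtype=np.intp)
        if pi.shape != wl.shape:
            raise ValueError("partner index must align with wavelengths")
        if np.any(pi == np.arange(wl.size)):
            raise ValueError("partner map must have no fixed points")
        ps = self.partner_score
        if ps is not None:
            ps = np.asarray(ps, dtype=float)
            if ps.shape != wl.shape:
                raise ValueError("partner scores must align with wavelengths")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "partner_index", pi)
        object.__setattr__(self, "partner_score", ps)

    @property
    def domain(self) -> tuple:
        return tuple(self.wavelengths)

    @property
    def partner(self) -> dict:
        return {
            float(w): float(self.wavelengths[self.partner_index[i]])
            for i, w in enumerate(self.wavelengths)
        }

    @property
    def score(self) -> dict:
        if self.partner_score is None:
            return {}
        return {
            float(w): float(self.partner_score[i])
            for i, w in enumerate(self.wavelengths)
        }

    def index_of(self, wavelength: float) -> int:
        i = int(np.searchsorted(self.wavelengths, wavelength))
        if i >= self.wavelengths.size or self.wavelengths[i] != wavelength:
            raise KeyError(f"wavelength {wavelength} nm not in partner-map domain")
        return i

    def __call__(self, wavelength: float) -> float:
        return float(self.wavelengths[self.partner_index[self.index_of(wavelength)]])


def blr_loocv_secv(x_i, x_k, y) -> float:
    """LOOCV SECV of ``y ~ b0 + b1*x_i + b2*x_k`` via the leverage identity.

    Returns +inf for non-identifiable pairs (collinear or constant
    predictors, or a leverage at 1).
    """
    x_i = np.asarray(x_i, dtype=float)
    x_k = np.asarray(x_k, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if x_i.shape != (n,) or x_k.shape != (n,):
        raise ValueError("x_i, x_k and y must be equal-length vectors")
    if n < 4:
        raise ValueError("pair scoring needs at least 4 samples (3 parameters)")
    xc = x_i - x_i.mean()
    zc = x_k - x_k.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    szz = float(zc @ zc)
    sxz = float(xc @ zc)
    sxy = float(xc @ yc)
    szy = float(zc @ yc)
    det = sxx * szz - sxz * sxz
    if det <= _DET_RTOL * max(sxx * szz, 1e-300):
        return np.inf
    b1 = (szz * sxy - sxz * szy) / det
    b2 = (sxx * szy - sxz * sxy) / det
    resid = yc - b1 * xc - b2 * zc
    lev = 1.0 / n + (szz * xc * xc - 2.0 * sxz * xc * zc + sxx * zc * zc) / det
    if np.any(lev >= 1.0 - _LEVERAGE_TOL):
        return np.inf
    press = resid / (1.0 - lev)
    return float(np.sqrt(np.mean(press * press)))


def _score_row(Xc, yc, G, sxy_all, i, n):
    """Scores of all pairs (i, k) at once; NaN at k=i, +inf where degenerate."""
    szz = np.diag(G)
    sxx = G[i, i]
    sxz = G[i]
    det = sxx * szz - sxz * sxz
    bad = det <= _DET_RTOL * np.maximum(sxx * szz, 1e-300)
    safe_det = np.where(bad, 1.0, det)
    b1 = (szz * sxy_all[i] - sxz * sxy_all) / safe_det
    b2 = (sxx * sxy_all - sxz * sxy_all[i]) / safe_det
    xi = Xc[:, i]
    resid = yc[:, None] - np.outer(xi, b1) - Xc * b2[None, :]
    lev = (
        1.0 / n
        + (szz * (xi * xi)[:, None] - 2.0 * sxz * (xi[:, None] * Xc) + sxx * Xc * Xc)
        / safe_det
    )
    bad |= np.any(lev >= 1.0 - _LEVERAGE_TOL, axis=0)
    press = resid / np.clip(1.0 - lev, 1e-300, None)
    row = np.sqrt(np.mean(press * press, axis=0))
    row[bad] = np.inf
    row[i] = np.nan
    return row


def pairwise_scores(data: SpectraSet) -> PairScoreMatrix:
    """Score every unordered wavelength pair of ``data`` by BLR LOOCV.

    Each pair is computed once (upper triangle) and mirrored, so the result
    is bit-exactly symmetric.
    """
    n, N = data.absorbance.shape
    if n < 4:
        raise ValueError("pair scoring needs at least 4 samples")
    if N < 2:
        raise ValueError("pair scoring needs at least 2 wavelengths")
    X = data.absorbance
    y = data.reference
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    G = Xc.T @ Xc
    sxy_all = Xc.T @ yc
    scores = np.full((N, N), np.nan)
    for i in range(N - 1):
        row = _score_row(Xc, yc, G, sxy_all, i, n)
        scores[i, i + 1 :] = row[i + 1 :]
    iu = np.triu_indices(N, k=1)
    scores[(iu[1], iu[0])] = scores[iu]
    return PairScoreMatrix(wavelengths=data.wavelengths, scores=scores)


def best_partner_map(scores: PairScoreMatrix) -> PartnerMap:
    """Map every wavelength to its best partner (row argmin, ties to smaller nm)."""
    S = scores.scores.copy()
    N = S.shape[0]
    np.fill_diagonal(S, np.inf)
    S[~np.isfinite(S)] = np.inf
    finite_rows = np.isfinite(S).any(axis=1)
    if not finite_rows.all():
        lam = scores.wavelengths[int(np.flatnonzero(~finite_rows)[0])]
        raise ValueError(
            f"wavelength {lam} nm has no identifiable pair; cannot assign a partner"
        )
    # argmin returns the first minimum; rows are in increasing-nm order,
    # so ties break toward the smaller wavelength
    partner_index = np.argmin(S, axis=1)
    best = S[np.arange(N), partner_index]
    return PartnerMap(
        wavelengths=scores.wavelengths,
        partner_index=partner_index,
        partner_score=best,
    )
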