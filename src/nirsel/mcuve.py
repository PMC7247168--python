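"""Monte Carlo uninformative variable elimination with PLS.

Artificial near-zero noise columns are appended to the spectra; many PLS
models are fitted on random calibration subsets; each variable's stability
(mean of its regression coefficients across runs divided by their standard
deviation) is compared against the noise columns.  Real variables whose
|stability| beats the noise cutoff survive.  The whole procedure is rerun
several times with fresh seeds and the rerun with minimum final SECV is
reported.

The cutoff rule (a quantile of the noise |stability| distribution, default
the maximum) and the calibration fraction per Monte Carlo run (default 0.8
without replacement) are the method's least-specified knobs; both are
configurable on :class:`McUveConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from nirsel.dataset import SpectraSet
from nirsel.pls import fit_pls, r_pcv, secv, select_factors
from nirsel.results import SelectionResult

__all__ = ["StabilityProfile", "McUveConfig", "augment_noise", "compute_stability", "run_mcuve"]

logger = logging.getLogger(__name__)

_NOISE_SCALE = 1e-10  # relative to mean |absorbance|


@dataclass(frozen=True)
class StabilityProfile:
    """Per-variable coefficient stability across Monte Carlo subset models."""

    labels: tuple
    stability: np.ndarray
    noise_mask: np.ndarray
    n_runs: int
    calibration_fraction: float
    n_factors: int

    def __post_init__(self):
        st = np.asarray(self.stability, dtype=float)
        mask = np.asarray(self.noise_mask, dtype=bool)
        if st.shape != mask.shape or len(self.labels) != st.size:
            raise ValueError("labels, stability and noise mask must align")
        object.__setattr__(self, "stability", st)
        object.__setattr__(self, "noise_mask", mask)
        object.__setattr__(self, "labels", tuple(self.labels))


@dataclass(frozen=True)
class McUveConfig:
    n_runs: int = 500
    n_reruns: int = 50
    calibration_fraction: float = 0.8
    factor_grid: tuple = tuple(range(1, 31))
    n_noise: int = None  # default: one noise column per real variable
    cutoff_quantile: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.calibration_fraction < 1:
            raise ValueError("calibration fraction must be in (0, 1)")
        if not 0 < self.cutoff_quantile <= 1:
            raise ValueError("cutoff quantile must be in (0, 1]")
        object.__setattr__(self, "factor_grid", tuple(int(f) for f in self.factor_grid))


def augment_noise(X, n_noise: int, rng) -> tuple:
    """Append ``n_noise`` columns of tiny uniform noise; returns (X_aug, mask).

    Noise amplitude is 1e-10 of the mean absolute absorbance, so the noise
    columns are numerically inert yet produce nonzero coefficients whose
    stability calibrates the elimination cutoff.
    """
    X = np.asarray(X, dtype=float)
    if n_noise < 1:
        raise ValueError("need at least one artificial noise column")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    scale = _NOISE_SCALE * max(float(np.mean(np.abs(X))), np.finfo(float).tiny)
    noise = rng.uniform(0.0, scale, size=(X.shape[0], n_noise))
    mask = np.zeros(X.shape[1] + n_noise, dtype=bool)
    mask[X.shape[1] :] = True
    return np.hstack([X, noise]), mask


def compute_stability(
    X_aug,
    y,
    n_runs: int,
    fraction: float,
    n_factors: int,
    rng,
    labels=None,
    noise_mask=None,
) -> StabilityProfile:
    """Coefficient stability of PLS models on random calibration subsets.

    Each run draws ``round(fraction * n)`` samples without replacement and
    fits a PLS model with ``n_factors`` components; stability is the
    across-run mean/SD ratio of each variable's coefficient.  Degenerate
    subsets (zero-variance y) are resampled and logged.
    """
    X_aug = np.asarray(X_aug, dtype=float)
    y = np.asarray(y, dtype=float)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n, p = X_aug.shape
    if n_runs < 2:
        raise ValueError("stability needs at least 2 Monte Carlo runs")
    n_cal = int(round(fraction * n))
    if n_cal < n_factors + 2:
        raise ValueError(
            f"calibration subsets of {n_cal} samples cannot support "
            f"{n_factors} factors"
        )
    coefs = np.empty((n_runs, p))
    for r in range(n_runs):
        for _ in range(100):
            idx = rng.choice(n, size=n_cal, replace=False)
            if np.ptp(y[idx]) > 0:
                break
            logger.warning("degenerate Monte Carlo subset (constant y); resampled")
        else:
            raise ValueError("could not draw a non-degenerate calibration subset")
        model = fit_pls(X_aug[idx], y[idx], min(n_factors, min(n_cal - 1, p)))
        coefs[r] = model.coef
    mean = coefs.mean(axis=0)
    sd = coefs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stability = np.where(sd > 0, mean / sd, np.nan)
    if labels is None:
        labels = tuple(str(j) for j in range(p))
    if noise_mask is None:
        noise_mask = np.zeros(p, dtype=bool)
    return StabilityProfile(
        labels=tuple(labels),
        stability=stability,
        noise_mask=noise_mask,
        n_runs=n_runs,
        calibration_fraction=fraction,
        n_factors=n_factors,
    )


def run_mcuve(data: SpectraSet, config: McUveConfig = McUveConfig()) -> SelectionResult:
    """Full elimination procedure with reruns; reports the minimum-SECV rerun.

    Per rerun: the working factor count is the full-data LOOCV optimum over
    the factor grid; noise columns are appended; stability is computed over
    ``config.n_runs`` subset models; real variables with |stability| above
    the noise cutoff are retained; the final model re-tunes the factor count
    on the retained columns.  Reruns with an empty retained set are
    discarded (an error only if all are).
    """
    X = data.absorbance
    y = data.reference
    n, N = X.shape
    n_noise = config.n_noise if config.n_noise is not None else N
    master = np.random.default_rng(config.seed)
    rerun_seeds = master.integers(0, 2**63 - 1, size=config.n_reruns)

    # working factor count: full-data LOOCV optimum, fixed across reruns
    f_work, _ = select_factors(X, y, config.factor_grid)

    best = None
    n_discarded = 0
    for rerun, seed in enumerate(rerun_seeds):
        rng = np.random.default_rng(seed)
        X_aug, noise_mask = augment_noise(X, n_noise, rng)
        labels = [f"{w:g}" for w in data.wavelengths] + [
            f"noise_{j}" for j in range(n_noise)
        ]
        profile = compute_stability(
            X_aug,
            y,
            config.n_runs,
            config.calibration_fraction,
            f_work,
            rng,
            labels=labels,
            noise_mask=noise_mask,
        )
        noise_abs = np.abs(profile.stability[noise_mask])
        noise_abs = noise_abs[np.isfinite(noise_abs)]
        cutoff = float(np.quantile(noise_abs, config.cutoff_quantile))
        real_abs = np.abs(profile.stability[:N])
        retained = np.flatnonzero(np.nan_to_num(real_abs) > cutoff)
        if retained.size == 0:
            logger.warning("rerun %d retained no variables; discarded", rerun)
            n_discarded += 1
            continue
        f_final, record = select_factors(X[:, retained], y, config.factor_grid)
        s = secv(record)
        if best is None or s < best[0]:
            best = (s, r_pcv(record), f_final, retained, cutoff, rerun)
    if best is None:
        raise ValueError("every rerun retained an empty variable set")
    s, r, f_final, retained, cutoff, rerun = best
    return SelectionResult(
        method="mc-uve-pls",
        wavelengths=tuple(data.wavelengths[retained]),
        n_factors=f_final,
        secv=s,
        r_pcv=r,
        extras={
            "cutoff": cutoff,
            "best_rerun": rerun,
            "n_reruns": config.n_reruns,
            "n_discarded_reruns": n_discarded,
            "n_monte_carlo_runs": config.n_runs,
            "calibration_fraction": config.calibration_fraction,
            "seed": config.seed,
        },
    )
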