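"""Exhaustive moving-window PLS search over window start, width and factor count.

Every feasible (start wavelength I, window width N, factor count F) triple is
scored by LOOCV SECV and the global minimum wins.  Windows are N consecutive
grid points beginning at I; F values infeasible for a narrow window are
skipped rather than rejected.  Ties break toward smaller N, then smaller I,
then smaller F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nirsel.dataset import SpectraSet
from nirsel.pls import PredictionRecord, loocv_predict_multi, r_pcv, secv
from nirsel.results import SelectionResult

__all__ = ["WindowSpec", "window_grid", "search_mwpls"]


@dataclass(frozen=True)
class WindowSpec:
    """A window of ``n_wavelengths`` consecutive grid points starting at ``initial``."""

    initial: float
    n_wavelengths: int
    start_index: int

    def slice(self):
        return slice(self.start_index, self.start_index + self.n_wavelengths)


def window_grid(grid, initial_set, width_set):
    """All (I, N) windows that fit on the grid, in I-major, N-minor order.

    Out-of-range combinations are silently excluded; an empty result is an
    error.
    """
    grid = np.asarray(grid, dtype=float)
    widths = sorted({int(n) for n in width_set if int(n) >= 1})
    windows = []
    for I in sorted({float(v) for v in initial_set}):
        pos = int(np.searchsorted(grid, I))
        if pos >= grid.size or grid[pos] != I:
            raise KeyError(f"initial wavelength {I} nm is not on the grid")
        for N in widths:
            if pos + N - 1 < grid.size:
                windows.append(WindowSpec(initial=I, n_wavelengths=N, start_index=pos))
    if not windows:
        raise ValueError("no feasible window for the given grids")
    return windows


def search_mwpls(
    data: SpectraSet,
    initial_set,
    width_set,
    factor_set,
    initial_stride: int = 1,
    keep_surface: bool = False,
) -> SelectionResult:
    """Find the (I, N, F) window minimizing LOOCV SECV.

    ``initial_stride`` subsamples the window-start grid (for smoke runs);
    stride 1 is the full traversal.  With ``keep_surface`` the per-window
    best SECV values are returned in ``extras['surface']`` as
    ``[I, N, F, secv]`` rows.
    """
    initials = sorted({float(v) for v in initial_set})[:: max(1, int(initial_stride))]
    windows = window_grid(data.wavelengths, initials, width_set)
    factors = sorted({int(f) for f in factor_set})
    if not factors:
        raise ValueError("factor set is empty")
    n = data.n_samples
    y = data.reference

    best = None  # (secv, N, I, F, record)
    surface = [] if keep_surface else None
    for w in windows:
        bound = min(n - 2, w.n_wavelengths)
        feasible = [f for f in factors if 1 <= f <= bound]
        if not feasible:
            continue
        X = data.absorbance[:, w.slice()]
        preds = loocv_predict_multi(X, y, max(feasible))
        win_best = None
        for f in feasible:
            d = preds[:, f - 1] - y
            s = float(np.sqrt(np.mean(d * d)))
            key = (s, w.n_wavelengths, w.initial, f)
            if best is None or key < best[0]:
                best = (key, preds[:, f - 1].copy(), w)
            if win_best is None or s < win_best[1]:
                win_best = (f, s)
        if surface is not None and win_best is not None:
            surface.append([w.initial, w.n_wavelengths, win_best[0], win_best[1]])
    if best is None:
        raise ValueError("no feasible (window, factor) combination")
    key, pred, w = best
    record = PredictionRecord(measured=y, predicted=pred)
    extras = {"initial": w.initial, "window_width": w.n_wavelengths}
    if surface is not None:
        extras["surface"] = surface
    return SelectionResult(
        method="mw-pls",
        wavelengths=tuple(data.wavelengths[w.slice()]),
        n_factors=key[3],
        secv=secv(record),
        r_pcv=r_pcv(record),
        extras=extras,
    )
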