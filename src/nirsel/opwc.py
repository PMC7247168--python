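"""Best-partner projection iteration to a stable wavelength combination.

The best-partner map f is computed once over the full screening domain;
iteration then repeatedly takes the image of the current set under that
fixed map.  Because each image is a subset of its argument's image chain,
the sets are nested and the iteration reaches a fixed point in at most N
steps, where f restricted to the stable set is a bijection (every stable
wavelength is the best partner of another stable wavelength).
"""

from __future__ import annotations

import numpy as np

from nirsel.dataset import SpectraSet, subset_wavelengths
from nirsel.partner import PairScoreMatrix, PartnerMap, best_partner_map, pairwise_scores
from nirsel.pls import r_pcv, secv, select_factors
from nirsel.results import ProjectionTrace, SelectionResult

__all__ = ["project", "run_opwc", "cycle_decomposition"]


def project(current, partner_map: PartnerMap) -> frozenset:
    """Image of ``current`` under the fixed best-partner map, deduplicated."""
    wl = partner_map.wavelengths
    pidx = partner_map.partner_index
    out = set()
    for lam in current:
        i = partner_map.index_of(float(lam))
        out.add(float(wl[pidx[i]]))
    return frozenset(out)


def iterate_projection(partner_map: PartnerMap, evaluate=None) -> ProjectionTrace:
    """Iterate image-taking from the full domain until the set stops changing.

    ``evaluate``, if given, is called on each set (sorted tuple of nm) and
    must return ``(n_factors, secv)``; results are recorded in the trace.
    """
    current = frozenset(float(w) for w in partner_map.wavelengths)
    sets = [current]
    max_iter = len(current)
    for _ in range(max_iter + 1):
        image = project(current, partner_map)
        if image == current:
            break
        sets.append(image)
        current = image
    else:  # pragma: no cover - impossible by the nesting argument
        raise RuntimeError("projection failed to converge within N iterations")
    per_secv = per_f = None
    if evaluate is not None:
        per_f, per_secv = [], []
        for s in sets:
            f, s_val = evaluate(tuple(sorted(s)))
            per_f.append(f)
            per_secv.append(s_val)
        per_f, per_secv = tuple(per_f), tuple(per_secv)
    # append the converged repeat so the trace shows the stopping condition
    sets.append(current)
    if evaluate is not None:
        per_f = per_f + (per_f[-1],)
        per_secv = per_secv + (per_secv[-1],)
    return ProjectionTrace(sets=sets, per_set_secv=per_secv, per_set_factors=per_f)


def run_opwc(
    data: SpectraSet,
    factor_grid=range(1, 21),
    evaluate_trace: bool = False,
    scores: PairScoreMatrix = None,
) -> SelectionResult:
    """Run the full selection: pair scores -> partner map -> iterate -> final PLS.

    Parameters
    ----------
    data : SpectraSet
        Spectra and reference values; needs >= 4 samples and >= 2 wavelengths.
    factor_grid : iterable of int
        Factor counts searched for the final (and, optionally, per-set) model.
    evaluate_trace : bool
        If True, fit a PLS model (minimum-SECV factor count) on every set of
        the projection trace — diagnostic, not part of selection.
    scores : PairScoreMatrix, optional
        Precomputed pair scores (e.g. from a cache); must match the grid.
    """
    if scores is None:
        scores = pairwise_scores(data)
    elif not np.array_equal(scores.wavelengths, data.wavelengths):
        raise ValueError("cached score matrix does not match the data grid")
    pmap = best_partner_map(scores)

    evaluate = None
    if evaluate_trace:

        def evaluate(wavelength_set):
            sub = subset_wavelengths(data, wavelength_set)
            f, rec = select_factors(sub.absorbance, sub.reference, factor_grid)
            return f, secv(rec)

    trace = iterate_projection(pmap, evaluate=evaluate)
    selected = trace.sets[-1]
    sub = subset_wavelengths(data, selected)
    f_best, record = select_factors(sub.absorbance, sub.reference, factor_grid)
    return SelectionResult(
        method="opwc-pls",
        wavelengths=selected,
        n_factors=f_best,
        secv=secv(record),
        r_pcv=r_pcv(record),
        trace=trace,
    )


def cycle_decomposition(partner_map: PartnerMap, stable_set):
    """Partition a set closed under f into its disjoint f-cycles.

    Returns a list of tuples; each tuple lists one cycle's wavelengths in
    traversal order starting from its smallest member.
    """
    stable = sorted(float(w) for w in stable_set)
    stable_f = frozenset(stable)
    nxt = {}
    for lam in stable:
        img = partner_map(lam)
        if img not in stable_f:
            raise ValueError(
                f"set is not closed under the partner map: f({lam}) = {img} "
                "is outside the set"
            )
        nxt[lam] = img
    cycles = []
    unvisited = set(stable)
    for start in stable:  # ascending, so cycles are found smallest-first
        if start not in unvisited:
            continue
        path = []
        node = start
        seen_at = {}
        while node not in seen_at:
            seen_at[node] = len(path)
            path.append(node)
            node = nxt[node]
        cycle = path[seen_at[node] :]
        if len(cycle) != len(path):
            raise ValueError(
                "set is closed but not a union of cycles; the partner map is "
                "not a bijection on it"
            )
        if len(cycle) == 1:
            raise AssertionError("1-cycle found: the partner map has a fixed point")
        k = cycle.index(min(cycle))
        cycles.append(tuple(cycle[k:] + cycle[:k]))
        unvisited.difference_update(cycle)
    return cycles
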