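"""Wavelength-indexed spectra tables with paired reference values.

The on-disk dialect is a comma-delimited, UTF-8 wide table: first column is
the sample id, one named column holds the reference analyte value, and every
other header cell must parse as a numeric wavelength in nm.  Floats are
written with :func:`repr`, so a write/read round trip is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "SpectraFormatError",
    "read_spectra_table",
    "write_spectra_table",
    "subset_wavelengths",
    "average_replicates",
]


class SpectraFormatError(ValueError):
    """Raised when a spectra table violates the expected wide format."""


@dataclass(frozen=True)
class SpectraSet:
    """An absorbance matrix on a common wavelength grid plus reference values.

    Attributes
    ----------
    wavelengths : ndarray of shape (N,)
        Strictly increasing grid points in nm.
    absorbance : ndarray of shape (n_samples, N)
        Absorbance, one row per sample.
    reference : ndarray of shape (n_samples,)
        Analyte reference value for each sample (e.g. g/L).
    sample_ids : tuple of str
        One label per sample.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    reference: np.ndarray
    sample_ids: tuple = field(default=())

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        ref = np.asarray(self.reference, dtype=float)
        if ab.ndim != 2:
            raise SpectraFormatError("absorbance must be a 2-D matrix")
        if wl.ndim != 1 or wl.size != ab.shape[1]:
            raise SpectraFormatError(
                f"{wl.size} wavelengths but {ab.shape[1]} absorbance columns"
            )
        if ref.ndim != 1 or ref.size != ab.shape[0]:
            raise SpectraFormatError(
                f"{ref.size} reference values but {ab.shape[0]} absorbance rows"
            )
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise SpectraFormatError("wavelengths must be strictly increasing")
        ids = tuple(str(s) for s in self.sample_ids) or tuple(
            str(i) for i in range(ab.shape[0])
        )
        if len(ids) != ab.shape[0]:
            raise SpectraFormatError(
                f"{len(ids)} sample ids but {ab.shape[0]} absorbance rows"
            )
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size


def read_spectra_table(path, reference_column: str = "ref") -> SpectraSet:
    """Read a wide CSV spectra table into a :class:`SpectraSet`.

    The first column is taken as the sample id; ``reference_column`` names
    the reference-value column; every remaining header must parse as a
    numeric wavelength.  Wavelength columns may appear in any order and are
    normalized to increasing order.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 3:
        raise SpectraFormatError(
            "table needs at least an id column, one wavelength column and "
            "the reference column"
        )
    id_col = df.columns[0]
    if reference_column not in df.columns:
        raise SpectraFormatError(
            f"reference column {reference_column!r} not found in header"
        )
    wl_cols = [c for c in df.columns if c not in (id_col, reference_column)]
    wavelengths = []
    for c in wl_cols:
        try:
            wavelengths.append(float(c))
        except ValueError:
            raise SpectraFormatError(
                f"header cell {c!r} is neither the id, the reference column "
                "nor a numeric wavelength"
            ) from None
    wavelengths = np.asarray(wavelengths)
    if np.unique(wavelengths).size != wavelengths.size:
        raise SpectraFormatError("duplicate wavelength columns in header")

    order = np.argsort(wavelengths)
    absorbance = np.empty((df.shape[0], wavelengths.size))
    for out_j, j in enumerate(order):
        col = pd.to_numeric(df[wl_cols[j]], errors="coerce")
        bad = col.isna() & ~df[wl_cols[j]].isna()
        bad |= df[wl_cols[j]].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SpectraFormatError(
                f"non-numeric absorbance value at row {row}, "
                f"column {wl_cols[j]!r}"
            )
        absorbance[:, out_j] = col.to_numpy(dtype=float)

    ref = pd.to_numeric(df[reference_column], errors="coerce")
    if ref.isna().any():
        row = int(np.flatnonzero(ref.isna().to_numpy())[0])
        raise SpectraFormatError(
            f"non-numeric reference value at row {row}"
        )
    return SpectraSet(
        wavelengths=wavelengths[order],
        absorbance=absorbance,
        reference=ref.to_numpy(dtype=float),
        sample_ids=tuple(str(s) for s in df[id_col]),
    )


def write_spectra_table(data: SpectraSet, path, reference_column: str = "ref") -> None:
    """Write ``data`` in the wide CSV dialect accepted by :func:`read_spectra_table`.

    Floats are serialized with :func:`repr` so the round trip is exact.
    """
    if data.n_samples < 1:
        raise SpectraFormatError("refusing to write a table with no samples")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        header = ["id"] + [repr(float(w)) for w in data.wavelengths]
        header.append(reference_column)
        fh.write(",".join(header) + "\n")
        for i in range(data.n_samples):
            cells = [data.sample_ids[i]]
            cells.extend(repr(float(v)) for v in data.absorbance[i])
            cells.append(repr(float(data.reference[i])))
            fh.write(",".join(cells) + "\n")


def subset_wavelengths(data: SpectraSet, selection) -> SpectraSet:
    """Restrict ``data`` to the requested wavelengths (must all be on the grid)."""
    wanted = np.asarray(sorted(set(float(w) for w in selection)))
    pos = np.searchsorted(data.wavelengths, wanted)
    ok = (pos < data.n_wavelengths) & np.isclose(
        data.wavelengths[np.minimum(pos, data.n_wavelengths - 1)], wanted
    )
    if not ok.all():
        missing = wanted[~ok][0]
        raise KeyError(f"wavelength {missing} nm is not on the grid")
    return SpectraSet(
        wavelengths=data.wavelengths[pos],
        absorbance=data.absorbance[:, pos],
        reference=data.reference,
        sample_ids=data.sample_ids,
    )


def average_replicates(data: SpectraSet, group_labels) -> SpectraSet:
    """Collapse replicate rows to per-group arithmetic means.

    Groups keep their order of first appearance; the output sample ids are
    the group labels.
    """
    labels = [str(g) for g in group_labels]
    if len(labels) != data.n_samples:
        raise ValueError(
            f"{len(labels)} group labels for {data.n_samples} samples"
        )
    seen: dict = {}
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(seen)
    inv = np.asarray([seen[lab] for lab in labels])
    n_groups = len(seen)
    counts = np.bincount(inv, minlength=n_groups).astype(float)
    absorbance = np.zeros((n_groups, data.n_wavelengths))
    np.add.at(absorbance, inv, data.absorbance)
    absorbance /= counts[:, None]
    reference = np.bincount(inv, weights=data.reference, minlength=n_groups) / counts
    return SpectraSet(
        wavelengths=data.wavelengths,
        absorbance=absorbance,
        reference=reference,
        sample_ids=tuple(seen),
    )
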