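"""Shared result containers and their JSON form."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ProjectionTrace", "SelectionResult"]


@dataclass(frozen=True)
class ProjectionTrace:
    """The shrinking sequence of wavelength sets produced by partner projection.

    ``sets[0]`` is the full screening domain; each later entry is the image
    of its predecessor under the fixed best-partner map.  ``per_set_secv``
    and ``per_set_factors`` are filled only when per-iteration PLS
    evaluation was requested.
    """

    sets: tuple
    per_set_secv: tuple = None
    per_set_factors: tuple = None

    def __post_init__(self):
        sets = tuple(tuple(sorted(s)) for s in self.sets)
        for a, b in zip(sets, sets[1:]):
            if not set(b) <= set(a):
                raise ValueError("projection trace sets must be nested")
        object.__setattr__(self, "sets", sets)

    @property
    def counts(self) -> tuple:
        return tuple(len(s) for s in self.sets)

    @property
    def n_iterations(self) -> int:
        return len(self.sets) - 1

    def to_dict(self) -> dict:
        out = {"counts": list(self.counts), "sets": [list(s) for s in self.sets]}
        if self.per_set_secv is not None:
            out["per_set_secv"] = list(self.per_set_secv)
        if self.per_set_factors is not None:
            out["per_set_factors"] = list(self.per_set_factors)
        return out


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a wavelength-selection run: the chosen subset and its model."""

    method: str
    wavelengths: tuple
    n_factors: int
    secv: float
    r_pcv: float
    trace: ProjectionTrace = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "wavelengths", tuple(float(w) for w in self.wavelengths)
        )

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths)

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "wavelengths": list(self.wavelengths),
            "n_wavelengths": self.n_wavelengths,
            "n_factors": self.n_factors,
            "secv": self.secv,
            "r_pcv": self.r_pcv,
        }
        if self.trace is not None:
            out["trace"] = self.trace.to_dict()
        if self.extras:
            out["extras"] = dict(self.extras)
        return out
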