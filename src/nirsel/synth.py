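"""Beer--Lambert mixture spectra with known ground truth.

Absorbance is a concentration-weighted sum of component spectra (sums of
Gaussian bands) plus a per-sample linear baseline and heteroscedastic
Gaussian channel noise, with configurable wavelength regions of inflated
noise.  The analyte's concentration is the reference value; the grid points
where the analyte's absorptivity exceeds a stated fraction of its peak form
the ground-truth "informative" mask used by recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from nirsel.dataset import SpectraSet

__all__ = [
    "Band",
    "ComponentSpec",
    "SynthConfig",
    "GroundTruth",
    "component_spectrum",
    "simulate_dataset",
    "serum_preset",
]


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: peak position (nm), width (nm), height."""

    center: float
    width: float
    amplitude: float


@dataclass(frozen=True)
class ComponentSpec:
    """A chemical component: its bands and its concentration distribution."""

    name: str
    bands: tuple
    conc_mean: float
    conc_sd: float
    conc_range: tuple = None  # (lo, hi) truncation, or None

    def __post_init__(self):
        object.__setattr__(self, "bands", tuple(self.bands))
        if self.conc_range is not None:
            lo, hi = self.conc_range
            if not lo <= self.conc_mean <= hi:
                raise ValueError(
                    f"component {self.name!r}: truncation range [{lo}, {hi}] "
                    f"excludes the mean {self.conc_mean}"
                )


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian channel noise with region-dependent inflation."""

    base_sd: float = 0.0
    regions: tuple = ()  # (lo_nm, hi_nm, multiplier) triples

    def sd_profile(self, grid: np.ndarray) -> np.ndarray:
        sd = np.full(grid.size, float(self.base_sd))
        for lo, hi, mult in self.regions:
            sd[(grid >= lo) & (grid <= hi)] *= mult
        return sd


@dataclass(frozen=True)
class SynthConfig:
    grid: tuple  # (start nm, stop nm, step nm)
    n_samples: int
    analyte: ComponentSpec
    interferents: tuple = ()
    baseline_offset: tuple = (0.0, 0.0)  # (mean, sd)
    baseline_slope: tuple = (0.0, 0.0)  # (mean, sd) over the full grid span
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    informative_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        start, stop, step = self.grid
        if step <= 0 or stop <= start:
            raise ValueError("grid must be (start, stop, step) with step > 0")
        if self.noise.base_sd < 0:
            raise ValueError("noise SD must be non-negative")
        wl = self.wavelengths()
        for comp in (self.analyte, *self.interferents):
            for band in comp.bands:
                if not wl[0] <= band.center <= wl[-1]:
                    raise ValueError(
                        f"band center {band.center} nm of {comp.name!r} is "
                        "outside the grid"
                    )
        object.__setattr__(self, "interferents", tuple(self.interferents))

    def wavelengths(self) -> np.ndarray:
        start, stop, step = self.grid
        n = int(round((stop - start) / step)) + 1
        return start + step * np.arange(n)


@dataclass(frozen=True)
class GroundTruth:
    """Per-component concentrations and the informative wavelength mask."""

    concentrations: dict
    informative_mask: np.ndarray
    analyte_spectrum: np.ndarray


def component_spectrum(spec: ComponentSpec, grid) -> np.ndarray:
    """Absorptivity of a component on the grid: sum of its Gaussian bands."""
    grid = np.asarray(grid, dtype=float)
    out = np.zeros(grid.size)
    for band in spec.bands:
        out += band.amplitude * np.exp(-0.5 * ((grid - band.center) / band.width) ** 2)
    return out


def _sample_concentrations(spec: ComponentSpec, n: int, rng) -> np.ndarray:
    if spec.conc_sd == 0:
        return np.full(n, spec.conc_mean)
    if spec.conc_range is None:
        return rng.normal(spec.conc_mean, spec.conc_sd, size=n)
    lo, hi = spec.conc_range
    a = (lo - spec.conc_mean) / spec.conc_sd
    b = (hi - spec.conc_mean) / spec.conc_sd
    return stats.truncnorm.rvs(
        a, b, loc=spec.conc_mean, scale=spec.conc_sd, size=n, random_state=rng
    )


def simulate_dataset(config: SynthConfig) -> tuple:
    """Generate a :class:`SpectraSet` and its :class:`GroundTruth`.

    Deterministic under ``config.seed``: identical configs give bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.wavelengths()
    n = config.n_samples
    components = (config.analyte, *config.interferents)
    conc = {c.name: _sample_concentrations(c, n, rng) for c in components}
    absorbance = np.zeros((n, grid.size))
    for c in components:
        absorbance += np.outer(conc[c.name], component_spectrum(c, grid))
    off_m, off_sd = config.baseline_offset
    slope_m, slope_sd = config.baseline_slope
    offsets = rng.normal(off_m, off_sd, size=n)
    slopes = rng.normal(slope_m, slope_sd, size=n)
    span = (grid - grid[0]) / (grid[-1] - grid[0])
    absorbance += offsets[:, None] + np.outer(slopes, span)
    sd = config.noise.sd_profile(grid)
    absorbance += rng.normal(size=(n, grid.size)) * sd

    analyte_spec = component_spectrum(config.analyte, grid)
    mask = analyte_spec >= config.informative_fraction * analyte_spec.max()
    data = SpectraSet(
        wavelengths=grid,
        absorbance=absorbance,
        reference=conc[config.analyte.name],
        sample_ids=tuple(f"s{i:04d}" for i in range(n)),
    )
    truth = GroundTruth(
        concentrations=conc, informative_mask=mask, analyte_spectrum=analyte_spec
    )
    return data, truth


def serum_preset(seed: int = 0) -> SynthConfig:
    """A serum-like recipe: 780-2498 nm at 2 nm (860 points), 230 samples.

    The analyte (a serum-protein fraction) absorbs in narrow bands inside
    1500-1850 and 2100-2350 nm; two broad interferents partially overlap it;
    channel noise is strongly inflated near 2000 and 2400 nm.  Analyte
    concentrations are Normal(27.477, 3.953) truncated to [18.70, 41.60] g/L.
    """
    analyte = ComponentSpec(
        name="analyte",
        bands=(
            Band(1550.0, 28.0, 6.0e-3),
            Band(1690.0, 22.0, 8.0e-3),
            Band(1740.0, 18.0, 7.0e-3),
            Band(2180.0, 24.0, 9.0e-3),
            Band(2300.0, 20.0, 6.5e-3),
        ),
        conc_mean=27.477,
        conc_sd=3.953,
        conc_range=(18.70, 41.60),
    )
    albumin_like = ComponentSpec(
        name="interferent_a",
        bands=(
            Band(1520.0, 60.0, 4.0e-3),
            Band(1720.0, 70.0, 3.5e-3),
            Band(2250.0, 80.0, 3.0e-3),
        ),
        conc_mean=45.0,
        conc_sd=4.0,
        conc_range=(30.0, 60.0),
    )
    water_like = ComponentSpec(
        name="interferent_b",
        bands=(
            Band(1440.0, 90.0, 0.35),
            Band(1930.0, 80.0, 0.9),
            Band(2450.0, 90.0, 0.5),
        ),
        conc_mean=1.0,
        conc_sd=0.004,
        conc_range=(0.98, 1.02),
    )
    return SynthConfig(
        grid=(780.0, 2498.0, 2.0),
        n_samples=230,
        analyte=analyte,
        interferents=(albumin_like, water_like),
        baseline_offset=(0.08, 0.015),
        baseline_slope=(0.05, 0.01),
        noise=NoiseSpec(
            base_sd=8.0e-4,
            regions=((1950.0, 2050.0, 100.0), (2350.0, 2450.0, 200.0)),
        ),
        seed=seed,
    )
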