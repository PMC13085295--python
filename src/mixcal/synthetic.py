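"""Synthetic UV-Vis spectra for a quaternary drug/impurity mixture.

The measured spectra behind the published calibration are not deposited, so
this module emulates the regime they create: four pure-component UV
absorption bands (bupropion, dextromethorphan, 3-chlorobenzoic acid and
N,N-dimethylaniline) that overlap severely in the 224-330 nm working
window, mixed bilinearly by the Beer-Lambert law at designed concentrations
and corrupted with seeded Gaussian instrument noise.

Pure absorptivity profiles are sums of Gaussian bands on the wavelength
grid, in AU per (ug/mL); mixture spectra are ``D = C @ S.T + E``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import SpectraMatrix, WavelengthGrid

__all__ = [
    "WavelengthGrid",
    "PureSpectraSet",
    "NoiseSpec",
    "DEFAULT_PEAK_PARAMS",
    "generate_pure_spectra",
    "simulate_mixture_spectra",
]

COMPONENTS = ("BUP", "DEX", "CBA", "DMA")

#: Default Gaussian band parameters per component: (center nm, width nm,
#: height in AU per ug/mL).  Chosen so that all four profiles absorb inside
#: 224-330 nm and overlap heavily there (pairwise cosine similarity of the
#: most-overlapping pair exceeds 0.7), reproducing the severe spectral
#: overlap that motivates multivariate calibration for this mixture.
DEFAULT_PEAK_PARAMS: dict[str, list[tuple[float, float, float]]] = {
    "BUP": [(250.0, 11.0, 0.052), (292.0, 16.0, 0.006)],
    "DEX": [(279.0, 10.0, 0.044), (227.0, 12.0, 0.032)],
    "CBA": [(234.0, 12.0, 0.088), (281.0, 14.0, 0.012)],
    "DMA": [(261.0, 13.0, 0.048), (306.0, 16.0, 0.030)],
}


@dataclass
class PureSpectraSet:
    """Pure-component absorptivity profiles on a common grid."""

    component_names: list[str]
    grid: WavelengthGrid
    absorptivity: np.ndarray = field(repr=False)  # n_points x k, AU per ug/mL
    peak_params: dict[str, list[tuple[float, float, float]]] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.absorptivity = np.asarray(self.absorptivity, dtype=float)
        k = len(self.component_names)
        if self.absorptivity.shape != (self.grid.n_points, k):
            raise ValueError(
                f"absorptivity shape {self.absorptivity.shape} does not match "
                f"{self.grid.n_points} points x {k} components"
            )
        if np.any(self.absorptivity < 0):
            raise ValueError("absorptivity must be non-negative everywhere")

    def restrict(self, lo_nm: float, hi_nm: float) -> "PureSpectraSet":
        """Profiles restricted to the closed window [lo_nm, hi_nm]."""
        w = self.grid.wavelengths
        mask = (w >= lo_nm - 1e-9) & (w <= hi_nm + 1e-9)
        if not mask.any():
            raise ValueError("window selects no grid points")
        sub = WavelengthGrid.from_wavelengths(w[mask])
        return PureSpectraSet(
            list(self.component_names), sub, self.absorptivity[mask], self.peak_params, self.seed
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Additive i.i.d. Gaussian instrument noise.

    Exactly one of ``sd_au`` (absolute absorbance SD) or ``sd_frac``
    (fraction of the maximum clean absorbance) is set; ``seed`` fully
    determines the realization.
    """

    sd_au: float | None = None
    sd_frac: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.sd_au is None) == (self.sd_frac is None):
            raise ValueError("set exactly one of sd_au / sd_frac")
        sd = self.sd_au if self.sd_au is not None else self.sd_frac
        if sd < 0:
            raise ValueError("noise SD must be non-negative")

    def sd_for(self, clean_max: float) -> float:
        if self.sd_au is not None:
            return float(self.sd_au)
        return float(self.sd_frac) * float(clean_max)


def _gaussian_profile(
    grid: WavelengthGrid, peaks: list[tuple[float, float, float]]
) -> np.ndarray:
    w = grid.wavelengths
    profile = np.zeros_like(w)
    for center, width, height in peaks:
        profile += height * np.exp(-0.5 * ((w - center) / width) ** 2)
    return profile


def generate_pure_spectra(
    grid: WavelengthGrid | None = None,
    peak_params: dict[str, list[tuple[float, float, float]]] | None = None,
    seed: int = 0,
) -> PureSpectraSet:
    """Build pure-component absorptivity profiles as Gaussian band sums.

    Parameters
    ----------
    grid : WavelengthGrid, optional
        Defaults to the 200-400 nm scan at 1 nm.
    peak_params : mapping component -> [(center, width, height), ...]
        Defaults to :data:`DEFAULT_PEAK_PARAMS`.
    seed : int
        Recorded in the returned set (the profiles themselves are a
        deterministic function of grid and peak parameters).
    """
    if grid is None:
        grid = WavelengthGrid(200.0, 400.0, 1.0)
    if peak_params is None:
        peak_params = DEFAULT_PEAK_PARAMS
    if not peak_params:
        raise ValueError("need at least one component")
    for name, peaks in peak_params.items():
        if not peaks:
            raise ValueError(f"component {name!r} has no peaks")
        for center, width, height in peaks:
            if not grid.lo_nm <= center <= grid.hi_nm:
                raise ValueError(
                    f"peak center {center} nm of {name!r} outside grid "
                    f"[{grid.lo_nm}, {grid.hi_nm}]"
                )
            if width <= 0 or height <= 0:
                raise ValueError(f"non-positive width/height in component {name!r}")
    names = list(peak_params)
    S = np.column_stack([_gaussian_profile(grid, peak_params[n]) for n in names])
    return PureSpectraSet(names, grid, S, dict(peak_params), seed)


def simulate_mixture_spectra(
    design, pure: PureSpectraSet, noise: NoiseSpec | None = None
) -> SpectraMatrix:
    """Bilinear Beer-Lambert mixture spectra ``D = C @ S.T + E``.

    Parameters
    ----------
    design : DesignTable
        Nominal concentrations; component order must match ``pure``.
    pure : PureSpectraSet
        Absorptivity profiles (AU per ug/mL).
    noise : NoiseSpec, optional
        Seeded additive Gaussian noise; omit for clean spectra.

    Rows of the output follow the design rows; sample ids are
    ``mix<id>`` from the design's mixture ids.
    """
    if list(design.component_names) != list(pure.component_names):
        raise ValueError(
            f"component order mismatch: design {design.component_names} "
            f"vs pure {pure.component_names}"
        )
    C = design.concentrations
    if np.any(C < 0):
        raise ValueError("negative concentration in design")
    D = C @ pure.absorptivity.T
    if noise is not None:
        sd = noise.sd_for(np.max(np.abs(D)) if D.size else 0.0)
        if sd > 0:
            rng = np.random.default_rng(noise.seed)
            D = D + rng.normal(0.0, sd, size=D.shape)
    ids = [f"mix{m}" for m in design.mixture_ids]
    return SpectraMatrix(ids, pure.grid, D)
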