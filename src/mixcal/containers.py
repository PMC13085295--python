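"""Core data containers shared across the package.

A :class:`WavelengthGrid` describes the abscissa of a UV-Vis scan; a
:class:`SpectraMatrix` holds a samples x wavelengths absorbance block
together with its grid and sample labels.  Both are small frozen-ish
dataclasses with validation on construction, in the spirit of AnnData /
xarray labelled containers but deliberately minimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WavelengthGrid", "SpectraMatrix"]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nanometres.

    Parameters
    ----------
    lo_nm, hi_nm : float
        Inclusive endpoints of the scan range.
    step_nm : float, default 1.0
        Grid spacing.

    The number of points is ``floor((hi - lo)/step) + 1`` so that both
    endpoints fall on the grid when the range is an exact multiple of the
    step (a 200-400 nm scan at 1 nm has 201 points).
    """

    lo_nm: float
    hi_nm: float
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not self.lo_nm < self.hi_nm:
            raise ValueError(f"need lo_nm < hi_nm, got [{self.lo_nm}, {self.hi_nm}]")
        if not self.step_nm > 0:
            raise ValueError(f"step_nm must be positive, got {self.step_nm}")

    @property
    def n_points(self) -> int:
        # int(floor(...)) with a tiny epsilon so exact multiples are not
        # dropped by floating-point round-off
        return int(np.floor((self.hi_nm - self.lo_nm) / self.step_nm + 1e-9)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.lo_nm + self.step_nm * np.arange(self.n_points)

    @classmethod
    def from_wavelengths(cls, wavelengths: np.ndarray) -> "WavelengthGrid":
        w = np.asarray(wavelengths, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("need a 1-d array of at least two wavelengths")
        steps = np.diff(w)
        if np.any(steps <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
            raise ValueError("wavelengths must be uniformly spaced")
        return cls(lo_nm=float(w[0]), hi_nm=float(w[-1]), step_nm=float(steps[0]))


@dataclass
class SpectraMatrix:
    """Samples x wavelengths absorbance matrix (the data matrix D).

    ``absorbance[i, j]`` is the absorbance (AU) of sample ``sample_ids[i]``
    at ``grid.wavelengths[j]``.
    """

    sample_ids: list[str]
    grid: WavelengthGrid
    absorbance: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.shape != (len(self.sample_ids), self.grid.n_points):
            raise ValueError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.grid.n_points} grid points"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def copy(self) -> "SpectraMatrix":
        return SpectraMatrix(list(self.sample_ids), self.grid, self.absorbance.copy())
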