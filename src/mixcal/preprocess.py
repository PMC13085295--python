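"""Spectral window selection and mean-centering with invertible state."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import SpectraMatrix, WavelengthGrid

__all__ = [
    "SpectraMatrix",
    "CenteringState",
    "select_window",
    "mean_center",
    "apply_centering",
    "undo_centering",
]


@dataclass
class CenteringState:
    """Column means subtracted during calibration, for re-application to
    validation/test spectra."""

    column_means: np.ndarray
    n_samples_fit: int

    def __post_init__(self) -> None:
        self.column_means = np.asarray(self.column_means, dtype=float).ravel()


def select_window(spectra: SpectraMatrix, lo_nm: float = 224.0, hi_nm: float = 330.0) -> SpectraMatrix:
    """Restrict to wavelengths in the closed interval [lo_nm, hi_nm].

    The default window retains the informative region of the quaternary
    mixture spectra: 107 points of a 1-nm grid between 224 and 330 nm.
    """
    if lo_nm > hi_nm:
        raise ValueError(f"lo_nm {lo_nm} > hi_nm {hi_nm}")
    g = spectra.grid
    if lo_nm < g.lo_nm - 1e-9 or hi_nm > g.hi_nm + 1e-9:
        raise ValueError(
            f"window [{lo_nm}, {hi_nm}] outside grid [{g.lo_nm}, {g.hi_nm}]"
        )
    w = spectra.wavelengths
    mask = (w >= lo_nm - 1e-9) & (w <= hi_nm + 1e-9)
    if not mask.any():
        raise ValueError("window selects no grid points")
    kept = w[mask]
    grid = _grid_from(kept, g.step_nm)
    return SpectraMatrix(list(spectra.sample_ids), grid, spectra.absorbance[:, mask])


class _SinglePointGrid(WavelengthGrid):
    """Degenerate one-wavelength grid (lo == hi)."""

    def __init__(self, wl: float, step: float):  # bypass frozen-dataclass init checks
        object.__setattr__(self, "lo_nm", float(wl))
        object.__setattr__(self, "hi_nm", float(wl))
        object.__setattr__(self, "step_nm", float(step))

    @property
    def n_points(self) -> int:  # pragma: no cover - trivial
        return 1

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array([self.lo_nm])


def _grid_from(kept: np.ndarray, step: float) -> WavelengthGrid:
    if kept.size == 1:
        return _SinglePointGrid(kept[0], step)
    return WavelengthGrid.from_wavelengths(kept)


def mean_center(spectra: SpectraMatrix) -> tuple[SpectraMatrix, CenteringState]:
    """Subtract per-wavelength column means; return centered data + state."""
    if spectra.n_samples < 2:
        raise ValueError("mean-centering needs at least 2 samples")
    means = spectra.absorbance.mean(axis=0)
    centered = SpectraMatrix(
        list(spectra.sample_ids), spectra.grid, spectra.absorbance - means
    )
    return centered, CenteringState(means, spectra.n_samples)


def apply_centering(spectra: SpectraMatrix, state: CenteringState) -> SpectraMatrix:
    """Center new spectra with stored calibration means."""
    if spectra.grid.n_points != state.column_means.size:
        raise ValueError(
            f"grid has {spectra.grid.n_points} points but state stores "
            f"{state.column_means.size} means"
        )
    return SpectraMatrix(
        list(spectra.sample_ids), spectra.grid, spectra.absorbance - state.column_means
    )


def undo_centering(spectra: SpectraMatrix, state: CenteringState) -> SpectraMatrix:
    """Add stored means back (inverse of :func:`apply_centering`)."""
    if spectra.grid.n_points != state.column_means.size:
        raise ValueError("grid/state length mismatch")
    return SpectraMatrix(
        list(spectra.sample_ids), spectra.grid, spectra.absorbance + state.column_means
    )
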