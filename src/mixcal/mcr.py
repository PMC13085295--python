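"""Multivariate curve resolution by alternating least squares (MCR-ALS).

The bilinear model ``D = C @ S.T + E`` is refined by alternating
least-squares solves for the concentration profiles C and the spectral
profiles S under chemically motivated constraints: non-negativity (solved
as constrained least squares, not clipped), horizontal unimodality, and a
correlation constraint that performs an inner least-squares calibration of
each resolved concentration column against known reference concentrations
of the calibration rows, fixing the intensity ambiguity and putting C in
real concentration units (ug/mL).

Test samples are quantified one at a time: the calibration matrix is
augmented with a single unknown spectrum, the ALS optimization is run with
the correlation constraint masked to the calibration rows, and the unknown
row of C is read off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .containers import SpectraMatrix
from .synthetic import PureSpectraSet

__all__ = [
    "McrConstraints",
    "McrResult",
    "MCRALS",
    "initialize_profiles",
    "run_mcr_als",
    "apply_unimodality",
    "apply_correlation_constraint",
    "lack_of_fit",
    "quantify_test_samples",
]


@dataclass
class McrConstraints:
    """Constraint configuration for the ALS refinement.

    ``correlation`` carries the reference concentrations (n_cal x k, ug/mL)
    of the rows flagged True in ``calibration_mask``; when set, each
    concentration column is mapped onto the references by an inner
    least-squares line every iteration.
    """

    nonneg_C: bool = True
    nonneg_S: bool = True
    unimodal_C: bool = False
    unimodal_S: bool = False
    unimodal_tol: float = 1.05
    correlation: np.ndarray | None = None
    calibration_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.nonneg_C or self.nonneg_S or self.unimodal_C or self.unimodal_S
                or self.correlation is not None):
            raise ValueError("at least one constraint must be active")
        if self.correlation is not None:
            self.correlation = np.atleast_2d(np.asarray(self.correlation, dtype=float))
            if self.calibration_mask is None:
                raise ValueError("correlation constraint needs a calibration_mask")
            self.calibration_mask = np.asarray(self.calibration_mask, dtype=bool)
            if self.correlation.shape[0] != int(self.calibration_mask.sum()):
                raise ValueError(
                    "correlation reference rows must match the number of "
                    "calibration-mask rows"
                )


@dataclass
class McrResult:
    """Resolved profiles and figures of merit of one ALS run."""

    C: np.ndarray = field(repr=False)
    S: np.ndarray = field(repr=False)
    E: np.ndarray = field(repr=False)
    lof_percent: float = 0.0
    r2_percent: float = 0.0
    n_iterations: int = 0
    converged: bool = False
    inner_calibration: list[tuple[float, float]] | None = None
    lof_history: list[float] = field(default_factory=list, repr=False)


def _data_matrix(D) -> np.ndarray:
    return D.absorbance if isinstance(D, SpectraMatrix) else np.atleast_2d(np.asarray(D, float))


def initialize_profiles(D, k: int, method: str = "purest_rows",
                        pure: PureSpectraSet | None = None) -> np.ndarray:
    """Initial spectral estimates S (n_points x k).

    ``pure_standards`` uses measured/simulated pure-component spectra
    restricted to the data window; ``purest_rows`` greedily picks the k
    most mutually dissimilar data rows (maximizing the Gram determinant of
    the normalized rows, seeded with the largest-norm row).
    """
    Dm = _data_matrix(D)
    if k < 1:
        raise ValueError("k must be >= 1")
    if method == "pure_standards":
        if pure is None:
            raise ValueError("pure_standards initialization requires a PureSpectraSet")
        if isinstance(D, SpectraMatrix):
            pure = pure.restrict(D.grid.lo_nm, D.grid.hi_nm)
        S = pure.absorptivity[:, :k]
        if S.shape != (Dm.shape[1], k):
            raise ValueError(
                "pure spectra do not match the data grid (restrict the pure "
                "set to the working window first)")
        return S.copy()
    if method != "purest_rows":
        raise ValueError(f"unknown initialization method {method!r}")
    rank = np.linalg.matrix_rank(Dm)
    if k > rank:
        warnings.warn(
            f"k={k} exceeds the numerical rank {rank} of D; rotational "
            "ambiguity expected", RuntimeWarning)
    norms = np.linalg.norm(Dm, axis=1)
    scale = np.where(norms > 0, norms, 1.0)
    N = Dm / scale[:, None]
    chosen = [int(np.argmax(norms))]
    while len(chosen) < k:
        best_r, best_det = None, -np.inf
        for r in range(Dm.shape[0]):
            if r in chosen:
                continue
            G = N[chosen + [r]] @ N[chosen + [r]].T
            det = np.linalg.det(G)
            if det > best_det:
                best_det, best_r = det, r
        chosen.append(best_r)
    return Dm[chosen].T.copy()


def apply_unimodality(profile, mode: str = "horizontal", tol: float = 1.05) -> np.ndarray:
    """Force a single maximum by the horizontal correction.

    Scanning outward-in on each side of the global maximum, any value that
    drops below the running bound by more than the tolerance factor is
    flattened to the bound, so secondary peaks become plateaus while the
    global maximum position is preserved.  Idempotent; a constant profile
    (single plateau) passes unchanged.
    """
    if mode != "horizontal":
        raise ValueError(f"unknown unimodality mode {mode!r}")
    v = np.asarray(profile, dtype=float).copy()
    if v.size <= 2:
        return v
    m = int(np.argmax(v))
    # ascending side: left edge -> max must be non-decreasing
    bound = v[0]
    for i in range(1, m):
        if v[i] * tol < bound:
            v[i] = bound
        bound = max(bound, v[i])
    # descending side: right edge -> max must be non-decreasing (right to left)
    bound = v[-1]
    for i in range(v.size - 2, m, -1):
        if v[i] * tol < bound:
            v[i] = bound
        bound = max(bound, v[i])
    return v


def apply_correlation_constraint(C_column, calibration_mask, reference
                                 ) -> tuple[np.ndarray, float, float]:
    """Inner calibration: map a resolved concentration column onto known
    reference concentrations.

    Fits ``reference ~ slope * C[mask] + intercept`` by least squares and
    transforms the whole column through that line, so calibration entries
    become the fitted references and test entries land in real units.
    """
    c = np.asarray(C_column, dtype=float).copy()
    mask = np.asarray(calibration_mask, dtype=bool)
    ref = np.asarray(reference, dtype=float)
    if mask.sum() < 2:
        raise ValueError("correlation constraint needs >= 2 calibration rows")
    if ref.size != int(mask.sum()):
        raise ValueError("reference length must match calibration rows")
    x = c[mask]
    if np.ptp(x) == 0:
        raise ValueError("resolved calibration entries have zero variance")
    slope, intercept = np.polyfit(x, ref, 1)
    return slope * c + intercept, float(slope), float(intercept)


def lack_of_fit(D, C, S) -> tuple[float, float]:
    """Percent lack of fit and explained variance of ``D ~ C @ S.T``.

    lof = 100 sqrt(sum(E^2)/sum(D^2)); R2 = 100 (1 - sum(E^2)/sum(D^2)).
    """
    Dm = _data_matrix(D)
    E = Dm - np.asarray(C) @ np.asarray(S).T
    ss_d = float(np.sum(Dm**2))
    if ss_d == 0:
        raise ValueError("all-zero data matrix")
    ratio = float(np.sum(E**2)) / ss_d
    return 100.0 * float(np.sqrt(ratio)), 100.0 * (1.0 - ratio)


def _solve_rows(A: np.ndarray, B: np.ndarray, nonneg: bool) -> np.ndarray:
    """Row-wise solve of ``B ~ X @ A.T`` for X (each row independently)."""
    k = A.shape[1]
    X = np.empty((B.shape[0], k))
    if nonneg:
        for i in range(B.shape[0]):
            X[i], _ = nnls(A, B[i])
        return X
    sol, _, rank, _ = np.linalg.lstsq(A, B.T, rcond=None)
    if rank < k:
        warnings.warn("rank-deficient least-squares solve; adding ridge jitter 1e-10",
                      RuntimeWarning)
        sol = np.linalg.solve(A.T @ A + 1e-10 * np.eye(k), A.T @ B.T)
    return sol.T


def run_mcr_als(D, init_S: np.ndarray, constraints: McrConstraints,
                conv_threshold_percent: float = 0.1, max_iter: int = 50) -> McrResult:
    """Alternating least-squares refinement of ``D = C @ S.T + E``.

    Each iteration solves for C (applying non-negativity, unimodality and
    the correlation inner calibration) then for S (non-negativity,
    unimodality), and evaluates the lack of fit; the best iterate is
    retained and iteration stops when the relative change in lof between
    consecutive iterations falls below ``conv_threshold_percent``/100.
    """
    Dm = _data_matrix(D)
    if np.any(~np.isfinite(Dm)):
        raise ValueError("NaN/inf in data matrix")
    if conv_threshold_percent <= 0:
        raise ValueError("convergence threshold must be positive")
    S = np.atleast_2d(np.asarray(init_S, dtype=float)).copy()
    if S.shape[0] != Dm.shape[1]:
        raise ValueError(
            f"init_S has {S.shape[0]} rows but D has {Dm.shape[1]} wavelengths")
    k = S.shape[1]

    def c_step(S_cur):
        C = _solve_rows(S_cur, Dm, constraints.nonneg_C)
        if constraints.unimodal_C:
            for j in range(k):
                C[:, j] = apply_unimodality(C[:, j], tol=constraints.unimodal_tol)
        inner = None
        if constraints.correlation is not None:
            inner = []
            for j in range(k):
                C[:, j], a, b = apply_correlation_constraint(
                    C[:, j], constraints.calibration_mask, constraints.correlation[:, j])
                inner.append((a, b))
        return C, inner

    history: list[float] = []
    best = None  # (lof, C, S, inner, iteration)
    prev_lof = None
    converged = False
    n_it = 0
    for n_it in range(1, max_iter + 1):
        C, inner = c_step(S)
        S_new = _solve_rows(C, Dm.T, constraints.nonneg_S)
        if constraints.unimodal_S:
            for j in range(k):
                S_new[:, j] = apply_unimodality(S_new[:, j], tol=constraints.unimodal_tol)
        S = S_new
        lof, _ = lack_of_fit(Dm, C, S)
        history.append(lof)
        if best is None or lof <= best[0] + 1e-12:
            best = (lof, C.copy(), S.copy(), inner, n_it)
        if prev_lof is not None:
            # denominator floored at 1e-9 % so a machine-zero residual
            # registers as converged rather than as relative chatter
            rel = abs(prev_lof - lof) / max(prev_lof, 1e-9)
            if rel < conv_threshold_percent / 100.0:
                converged = True
                break
        prev_lof = lof
    _, C, S, inner, _ = best
    E = Dm - C @ S.T
    lof, r2 = lack_of_fit(Dm, C, S)
    return McrResult(C, S, E, lof, r2, n_it, converged, inner, history)


def quantify_test_samples(calibration_D, test_D, constraints: McrConstraints,
                          init_S: np.ndarray | None = None,
                          pure: PureSpectraSet | None = None,
                          conv_threshold_percent: float = 0.1,
                          max_iter: int = 50) -> np.ndarray:
    """One-by-one quantification of unknown spectra.

    Each test spectrum is appended to the calibration matrix in turn, the
    ALS optimization is run with the correlation constraint masked to the
    calibration rows, and that sample's row of C is collected.  Results do
    not depend on the processing order of the test rows.
    """
    Dc = _data_matrix(calibration_D)
    Dt = _data_matrix(test_D)
    if Dc.shape[1] != Dt.shape[1]:
        raise ValueError("calibration and test grids differ")
    if constraints.correlation is None:
        raise ValueError("one-by-one quantification requires the correlation constraint")
    ref = constraints.correlation
    k = ref.shape[1]
    if init_S is None:
        method = "pure_standards" if pure is not None else "purest_rows"
        src = calibration_D if isinstance(calibration_D, SpectraMatrix) else Dc
        init_S = initialize_profiles(src, k, method=method, pure=pure)
    mask = np.r_[np.ones(Dc.shape[0], dtype=bool), [False]]
    preds = np.empty((Dt.shape[0], k))
    for i in range(Dt.shape[0]):
        D_aug = np.vstack([Dc, Dt[i]])
        cons = McrConstraints(
            nonneg_C=constraints.nonneg_C, nonneg_S=constraints.nonneg_S,
            unimodal_C=constraints.unimodal_C, unimodal_S=constraints.unimodal_S,
            unimodal_tol=constraints.unimodal_tol,
            correlation=ref, calibration_mask=mask)
        res = run_mcr_als(D_aug, init_S, cons, conv_threshold_percent, max_iter)
        preds[i] = res.C[-1]
    return preds


class MCRALS(BaseEstimator):
    """scikit-learn-style wrapper around the ALS resolver.

    ``fit(D, C_ref)`` resolves the calibration matrix (storing ``C_``,
    ``S_``, ``lof_percent_`` ...); ``predict(D_test)`` quantifies unknown
    spectra one by one with the correlation constraint.
    """

    def __init__(self, n_components: int = 4, nonneg_C: bool = True, nonneg_S: bool = True,
                 unimodal_C: bool = False, unimodal_S: bool = False,
                 unimodal_tol: float = 1.05, init: str = "purest_rows",
                 conv_threshold_percent: float = 0.1, max_iter: int = 50):
        self.n_components = n_components
        self.nonneg_C = nonneg_C
        self.nonneg_S = nonneg_S
        self.unimodal_C = unimodal_C
        self.unimodal_S = unimodal_S
        self.unimodal_tol = unimodal_tol
        self.init = init
        self.conv_threshold_percent = conv_threshold_percent
        self.max_iter = max_iter

    def _constraints(self, C_ref, mask) -> McrConstraints:
        return McrConstraints(
            nonneg_C=self.nonneg_C, nonneg_S=self.nonneg_S,
            unimodal_C=self.unimodal_C, unimodal_S=self.unimodal_S,
            unimodal_tol=self.unimodal_tol, correlation=C_ref, calibration_mask=mask)

    def fit(self, D, C_ref=None, pure: PureSpectraSet | None = None):
        Dm = _data_matrix(D)
        mask = np.ones(Dm.shape[0], dtype=bool) if C_ref is not None else None
        init_method = "pure_standards" if (pure is not None and self.init == "pure_standards") else "purest_rows"
        S0 = initialize_profiles(D, self.n_components, method=init_method, pure=pure)
        res = run_mcr_als(D, S0, self._constraints(C_ref, mask),
                          self.conv_threshold_percent, self.max_iter)
        self._D_fit = Dm
        self._C_ref = None if C_ref is None else np.atleast_2d(np.asarray(C_ref, float))
        self._pure = pure
        self._init_S = S0
        self.C_, self.S_, self.E_ = res.C, res.S, res.E
        self.lof_percent_, self.r2_percent_ = res.lof_percent, res.r2_percent
        self.n_iterations_, self.converged_ = res.n_iterations, res.converged
        self.inner_calibration_ = res.inner_calibration
        self.result_ = res
        return self

    def predict(self, D_test) -> np.ndarray:
        if self._C_ref is None:
            raise ValueError("predict requires the model fitted with reference "
                             "concentrations (correlation constraint)")
        cons = self._constraints(self._C_ref, np.ones(self._D_fit.shape[0], dtype=bool))
        return quantify_test_samples(
            self._D_fit, D_test, cons, init_S=self._init_S, pure=self._pure,
            conv_threshold_percent=self.conv_threshold_percent, max_iter=self.max_iter)
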