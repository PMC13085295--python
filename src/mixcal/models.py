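"""PCR and PLS multivariate calibration estimators.

Both estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes) and center X and Y
internally, restoring the concentration means at prediction.  PCR regresses
the responses on leading principal-component scores of the spectra; PLS is
the iterative NIPALS PLS2 construction with X- and Y-deflation, which
extracts latent variables maximizing spectral/concentration covariance.

Latent-variable counts are chosen by leave-one-out cross-validation
(:func:`loocv_select_lv`): each sample is left out in turn, the model is
refit from scratch (including re-centering) on the remainder, and the
pooled prediction error RMSECV is minimized over the candidate counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .containers import SpectraMatrix
from .preprocess import CenteringState

__all__ = [
    "PCRRegressor",
    "PLSRegressor",
    "CalibrationModel",
    "LvSelection",
    "fit_pcr",
    "fit_pls",
    "predict",
    "loocv_select_lv",
    "rmse",
]


def _as_2d(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


class _CenteredLinearRegressor(RegressorMixin, BaseEstimator):
    """Shared fit/predict plumbing: center X and Y, store a coefficient
    matrix mapping centered spectra to centered concentrations."""

    def __init__(self, n_components: int = 2, center: bool = True):
        self.n_components = n_components
        self.center = center

    def _center_xy(self, X, Y):
        X = _as_2d(X)
        Y = _as_2d(Y)
        if X.shape[0] != Y.shape[0]:
            raise ValueError(f"X has {X.shape[0]} rows but Y has {Y.shape[0]}")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise ValueError("non-finite values in X or Y")
        if self.center:
            self.x_mean_ = X.mean(axis=0)
            self.y_mean_ = Y.mean(axis=0)
        else:
            self.x_mean_ = np.zeros(X.shape[1])
            self.y_mean_ = np.zeros(Y.shape[1])
        return X - self.x_mean_, Y - self.y_mean_

    def predict(self, X) -> np.ndarray:
        X = _as_2d(X)
        if X.shape[1] != self.coef_.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects {self.coef_.shape[0]}"
            )
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_


class PCRRegressor(_CenteredLinearRegressor):
    """Principal component regression.

    The centered spectra are decomposed by SVD; the responses are regressed
    on the scores of the ``n_components`` leading components (ordered by
    decreasing singular value) and the coefficients are mapped back to
    wavelength space.

    Attributes
    ----------
    coef_ : (n_wavelengths, n_targets) array
    singular_values_ : singular values of the centered spectra
    components_ : (n_components, n_wavelengths) loading matrix
    """

    def fit(self, X, Y):
        Xc, Yc = self._center_xy(X, Y)
        a = int(self.n_components)
        if a < 0:
            raise ValueError("n_components must be >= 0")
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int(np.sum(s > max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0)))
        if a > rank:
            raise ValueError(
                f"n_components={a} exceeds the numerical rank {rank} of the "
                "centered calibration spectra"
            )
        self.singular_values_ = s
        self.components_ = Vt[:a]
        if a == 0:
            self.coef_ = np.zeros((Xc.shape[1], Yc.shape[1]))
        else:
            # scores T = U_a s_a; regression of Yc on T has closed form
            B_scores = (U[:, :a].T @ Yc) / s[:a, None]
            self.coef_ = Vt[:a].T @ B_scores
        self.n_components_ = a
        return self


class PLSRegressor(_CenteredLinearRegressor):
    """Partial least squares (NIPALS PLS2) regression.

    Latent variables are extracted one at a time by the NIPALS inner
    iteration; X is deflated by its loadings and Y by its regression on the
    scores, so the score path is fully deterministic.

    Attributes
    ----------
    coef_ : (n_wavelengths, n_targets) array
    x_weights_, x_loadings_ : (n_wavelengths, n_components)
    y_loadings_ : (n_targets, n_components)
    x_scores_ : (n_samples, n_components)
    """

    def __init__(self, n_components: int = 2, center: bool = True,
                 tol: float = 1e-10, max_iter: int = 500):
        super().__init__(n_components=n_components, center=center)
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, Y):
        Xc, Yc = self._center_xy(X, Y)
        a_max = int(self.n_components)
        if a_max < 0:
            raise ValueError("n_components must be >= 0")
        n, p = Xc.shape
        m = Yc.shape[1]
        if a_max > 0 and not np.any(Xc != 0):
            raise ValueError("centered X has zero variance; nothing to model")
        Xd, Yd = Xc.copy(), Yc.copy()
        W = np.zeros((p, a_max))
        P = np.zeros((p, a_max))
        Q = np.zeros((m, a_max))
        T = np.zeros((n, a_max))
        for a in range(a_max):
            u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
            if not np.any(u != 0):
                u = Yd[:, 0] + 1e-30
            for _ in range(self.max_iter):
                w = Xd.T @ u
                nw = np.linalg.norm(w)
                if nw == 0:
                    raise ValueError(
                        f"latent variable {a + 1}: X carries no remaining covariance"
                    )
                w /= nw
                t = Xd @ w
                tt = t @ t
                if tt == 0:
                    raise ValueError(f"latent variable {a + 1}: degenerate scores")
                q = Yd.T @ t / tt
                if m == 1:
                    break
                u_new = Yd @ q / (q @ q)
                if np.linalg.norm(u_new - u) <= self.tol * max(np.linalg.norm(u_new), 1e-300):
                    u = u_new
                    break
                u = u_new
            else:
                raise RuntimeError(
                    f"NIPALS inner loop for latent variable {a + 1} did not "
                    f"converge in {self.max_iter} iterations at tol {self.tol}"
                )
            p_load = Xd.T @ t / tt
            Xd = Xd - np.outer(t, p_load)
            Yd = Yd - np.outer(t, q)
            W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_load, q, t
        self.x_weights_, self.x_loadings_, self.y_loadings_, self.x_scores_ = W, P, Q, T
        if a_max == 0:
            self.coef_ = np.zeros((p, m))
        else:
            self.coef_ = W @ np.linalg.solve(P.T @ W, Q.T)
        self.n_components_ = a_max
        return self


@dataclass
class LvSelection:
    """Leave-one-out cross-validation curve and the chosen LV count."""

    candidate_lvs: list[int]
    rmsecv: np.ndarray
    rmsecv_per_component: np.ndarray = field(repr=False)
    chosen_lv: int = 0


@dataclass
class CalibrationModel:
    """A fitted multivariate calibration predictor with its preprocessing
    state (spectral and concentration means) and latent-variable count."""

    kind: str
    n_lv: int
    estimator: object
    training_meta: dict = field(default_factory=dict)

    @property
    def coef(self) -> np.ndarray:
        return self.estimator.coef_

    @property
    def x_centering(self) -> CenteringState:
        return CenteringState(self.estimator.x_mean_, self.training_meta.get("n_samples", 0))

    @property
    def y_means(self) -> np.ndarray:
        return self.estimator.y_mean_


def fit_pcr(X, Y, n_lv: int, **meta) -> CalibrationModel:
    """Fit a PCR calibration with ``n_lv`` principal components."""
    est = PCRRegressor(n_components=n_lv).fit(X, Y)
    meta.setdefault("n_samples", _as_2d(X).shape[0])
    return CalibrationModel("PCR", n_lv, est, meta)


def fit_pls(X, Y, n_lv: int, **meta) -> CalibrationModel:
    """Fit a NIPALS PLS2 calibration with ``n_lv`` latent variables."""
    est = PLSRegressor(n_components=n_lv).fit(X, Y)
    meta.setdefault("n_samples", _as_2d(X).shape[0])
    return CalibrationModel("PLS", n_lv, est, meta)


def predict(model: CalibrationModel, spectra) -> np.ndarray:
    """Predict concentrations (ug/mL) for spectra on the training window."""
    X = spectra.absorbance if isinstance(spectra, SpectraMatrix) else _as_2d(spectra)
    return model.estimator.predict(X)


def _loo_mean_predictor_errors(Y: np.ndarray) -> np.ndarray:
    # leaving sample i out, the mean of the rest misses y_i by (n/(n-1))(y_i - ybar)
    n = Y.shape[0]
    return (n / (n - 1)) * (Y - Y.mean(axis=0))


_FITTERS = {"PCR": PCRRegressor, "PLS": PLSRegressor}


def loocv_select_lv(X, Y, max_lv: int, fit: str = "PLS",
                    candidates: list[int] | None = None) -> LvSelection:
    """Choose the latent-variable count by leave-one-out cross-validation.

    For every candidate count, each sample is excluded in turn, the model
    (including centering) is refit on the remainder and the held-out
    prediction error accumulated; RMSECV pools the squared errors over all
    samples and components.  Ties (within 1e-12) resolve to the smallest
    count.  Candidate 0 denotes the mean-only predictor.
    """
    X, Y = _as_2d(X), _as_2d(Y)
    n, m = Y.shape
    if max_lv > n - 2:
        raise ValueError(f"max_lv={max_lv} too large for {n} samples (needs <= n-2)")
    if fit not in _FITTERS:
        raise ValueError(f"unknown model kind {fit!r}")
    if candidates is None:
        candidates = list(range(1, max_lv + 1))
    cls = _FITTERS[fit]
    sq = np.zeros((len(candidates), m))
    for i in range(n):
        keep = np.arange(n) != i
        Xtr, Ytr = X[keep], Y[keep]
        xi, yi = X[i], Y[i]
        for c, a in enumerate(candidates):
            if a == 0:
                err = yi - Ytr.mean(axis=0)
            else:
                est = cls(n_components=a).fit(Xtr, Ytr)
                err = est.predict(xi[None, :])[0] - yi
            sq[c] += err**2
    per_comp = np.sqrt(sq / n)
    pooled = np.sqrt(sq.sum(axis=1) / (n * m))
    best = pooled.min()
    chosen = min(a for a, r in zip(candidates, pooled) if r <= best + 1e-12)
    return LvSelection(list(candidates), pooled, per_comp, chosen)


def rmse(pred, nominal) -> np.ndarray:
    """Per-component root mean square error (RMSEC on the calibration set,
    RMSEP on the validation set)."""
    pred, nominal = _as_2d(pred), _as_2d(nominal)
    if pred.shape != nominal.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {nominal.shape}")
    if pred.shape[0] == 0:
        raise ValueError("need at least one sample")
    return np.sqrt(np.mean((pred - nominal) ** 2, axis=0))
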