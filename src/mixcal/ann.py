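"""Feed-forward linear-linear network trained by Levenberg-Marquardt.

The network maps a 107-point centered spectrum through ten hidden neurons
to the four component concentrations, with linear (purelin) transfer in
both layers, so it is algebraically a rank-constrained affine map
``y = W2 (W1 x + b1) + b2``.  Training nevertheless follows the classical
Levenberg-Marquardt procedure on the full Jacobian with a seeded
train/validation/test split and validation-based early stopping, because
the training trajectory (damping schedule, epoch history, best-validation
snapshot) is part of the modelling procedure being reproduced, not just
the final function.

The normal equations are solved in residual space,
``delta = J.T (J J.T + mu I)^-1 r``, which is exact for mu > 0 and much
cheaper than forming J.T J when the parameter count (1124 for 107-10-4)
exceeds the residual count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .containers import SpectraMatrix

__all__ = ["AnnModel", "TrainHistory", "AnnRegressor", "init_network",
           "train_lm", "ann_predict", "collapse_to_affine"]


@dataclass
class AnnModel:
    """Weights of a linear-linear feed-forward network."""

    W1: np.ndarray = field(repr=False)  # hidden x input
    b1: np.ndarray = field(repr=False)
    W2: np.ndarray = field(repr=False)  # output x hidden
    b2: np.ndarray = field(repr=False)
    transfer: tuple[str, str] = ("linear", "linear")
    seed: int = 0
    x_mean: np.ndarray | None = None
    y_mean: np.ndarray | None = None

    @property
    def n_input(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def n_output(self) -> int:
        return self.W2.shape[0]


@dataclass
class TrainHistory:
    """Per-epoch record of a Levenberg-Marquardt run."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    test_mse: list[float] = field(default_factory=list)
    mu: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stop_reason: str = ""


def init_network(seed: int = 0, n_input: int = 107, n_hidden: int = 10,
                 n_output: int = 4) -> AnnModel:
    """Seeded small random weights, uniform in +-0.5 scaled by fan-in."""
    rng = np.random.default_rng(seed)
    W1 = rng.uniform(-0.5, 0.5, size=(n_hidden, n_input)) / np.sqrt(n_input)
    b1 = rng.uniform(-0.5, 0.5, size=n_hidden) / np.sqrt(n_input)
    W2 = rng.uniform(-0.5, 0.5, size=(n_output, n_hidden)) / np.sqrt(n_hidden)
    b2 = rng.uniform(-0.5, 0.5, size=n_output) / np.sqrt(n_hidden)
    return AnnModel(W1, b1, W2, b2, seed=seed)


def _forward(model: AnnModel, X: np.ndarray) -> np.ndarray:
    H = X @ model.W1.T + model.b1
    return H @ model.W2.T + model.b2


def _pack(model: AnnModel) -> np.ndarray:
    return np.concatenate([model.W1.ravel(), model.b1, model.W2.ravel(), model.b2])


def _unpack(theta: np.ndarray, shape: AnnModel) -> AnnModel:
    h, p = shape.W1.shape
    o = shape.W2.shape[0]
    i = 0
    W1 = theta[i:i + h * p].reshape(h, p); i += h * p
    b1 = theta[i:i + h]; i += h
    W2 = theta[i:i + o * h].reshape(o, h); i += o * h
    b2 = theta[i:i + o]
    return AnnModel(W1, b1, W2, b2, shape.transfer, shape.seed, shape.x_mean, shape.y_mean)


def _jacobian(model: AnnModel, X: np.ndarray) -> np.ndarray:
    """Jacobian of the stacked residual vector (sample-major, output-minor)
    with respect to the packed parameters."""
    n, p = X.shape
    h, o = model.n_hidden, model.n_output
    H = X @ model.W1.T + model.b1  # n x h
    n_par = h * p + h + o * h + o
    J = np.zeros((n * o, n_par))
    for s in range(n):
        for k in range(o):
            r = s * o + k
            # dW1[j,i] = W2[k,j] * x[i]; db1[j] = W2[k,j]
            J[r, :h * p] = np.outer(model.W2[k], X[s]).ravel()
            J[r, h * p:h * p + h] = model.W2[k]
            # dW2[k,:] = H[s]; db2[k] = 1
            off = h * p + h
            J[r, off + k * h: off + (k + 1) * h] = H[s]
            J[r, off + o * h + k] = 1.0
    return J


def _split_indices(n: int, fractions: tuple[float, float, float], rng: np.random.Generator):
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    order = rng.permutation(n)
    n_tr = int(round(fractions[0] * n))
    n_va = int(round(fractions[1] * n))
    n_tr = max(1, min(n_tr, n - 2)) if fractions[1] > 0 and fractions[2] > 0 else n_tr
    return order[:n_tr], order[n_tr:n_tr + n_va], order[n_tr + n_va:]


def train_lm(model: AnnModel, X: np.ndarray, Y: np.ndarray,
             split: tuple[float, float, float] = (0.7, 0.15, 0.15),
             patience: int = 6, max_epochs: int = 1000, mse_goal: float = 0.0,
             mu0: float = 1e-3, mu_max: float = 1e10,
             seed: int | None = None) -> tuple[AnnModel, TrainHistory]:
    """Levenberg-Marquardt training with early stopping.

    An epoch proposes ``delta = -(J.T J + mu I)^-1 J.T r`` on the training
    partition; a step is accepted (and mu divided by 10) when it lowers the
    training MSE, otherwise mu is multiplied by 10 and the step retried.
    Training stops when the validation MSE has not improved for ``patience``
    consecutive epochs, when mu overflows ``mu_max``, at ``max_epochs``, or
    when the training MSE reaches ``mse_goal``; the returned model is the
    best-validation snapshot.
    """
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 samples to train")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate training data: all rows identical")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    idx_tr, idx_va, idx_te = _split_indices(n, split, rng)
    Xtr, Ytr = X[idx_tr], Y[idx_tr]
    Xva, Yva = X[idx_va], Y[idx_va]
    Xte, Yte = X[idx_te], Y[idx_te]

    def mse(m, Xp, Yp):
        if Xp.shape[0] == 0:
            return np.nan
        return float(np.mean((_forward(m, Xp) - Yp) ** 2))

    cur = model
    mu = mu0
    hist = TrainHistory()
    best_val = np.inf
    best_model = cur
    best_epoch = 0
    fails = 0
    stop = "max_epochs"
    for epoch in range(1, max_epochs + 1):
        tr_mse = mse(cur, Xtr, Ytr)
        if tr_mse <= mse_goal:
            stop = "goal"
            break
        r = (_forward(cur, Xtr) - Ytr).ravel()
        J = _jacobian(cur, Xtr)
        JJt = J @ J.T
        improved = False
        while mu <= mu_max:
            try:
                lam = np.linalg.solve(JJt + mu * np.eye(JJt.shape[0]), r)
            except np.linalg.LinAlgError:
                mu *= 10
                continue
            delta = -J.T @ lam
            trial = _unpack(_pack(cur) + delta, cur)
            if mse(trial, Xtr, Ytr) < tr_mse:
                cur = trial
                mu = max(mu / 10, 1e-20)
                improved = True
                break
            mu *= 10
        hist.train_mse.append(mse(cur, Xtr, Ytr))
        va = mse(cur, Xva, Yva)
        hist.val_mse.append(va)
        hist.test_mse.append(mse(cur, Xte, Yte))
        hist.mu.append(mu)
        if not improved:
            stop = "mu_max"
            break
        if np.isnan(va):  # no validation partition: track training instead
            va = hist.train_mse[-1]
        if va < best_val - 1e-300:
            best_val = va
            best_model = cur
            best_epoch = epoch
            fails = 0
        else:
            fails += 1
            if fails >= patience:
                stop = "validation_patience"
                break
    else:
        stop = "max_epochs"
    hist.best_epoch = best_epoch
    hist.stop_reason = stop
    if best_epoch == 0:
        best_model = cur
    return best_model, hist


def ann_predict(model: AnnModel, spectra_centered) -> np.ndarray:
    """Concentrations (ug/mL) from centered spectra, restoring stored
    concentration means when present."""
    X = spectra_centered.absorbance if isinstance(spectra_centered, SpectraMatrix) \
        else np.atleast_2d(np.asarray(spectra_centered, float))
    if X.shape[1] != model.n_input:
        raise ValueError(f"input width {X.shape[1]} != network input {model.n_input}")
    out = _forward(model, X)
    if model.y_mean is not None:
        out = out + model.y_mean
    return out


def collapse_to_affine(model: AnnModel) -> tuple[np.ndarray, np.ndarray]:
    """Equivalent affine map (A, c) with ``A = W2 W1`` (rank <= n_hidden)
    and ``c = W2 b1 + b2``."""
    if model.transfer != ("linear", "linear"):
        raise ValueError("collapse requires linear transfer in both layers")
    return model.W2 @ model.W1, model.W2 @ model.b1 + model.b2


class AnnRegressor(RegressorMixin, BaseEstimator):
    """scikit-learn-style wrapper: centers X and Y, trains by LM, predicts
    in concentration units."""

    def __init__(self, n_hidden: int = 10, split: tuple[float, float, float] = (0.7, 0.15, 0.15),
                 patience: int = 6, max_epochs: int = 1000, mse_goal: float = 0.0,
                 seed: int = 0):
        self.n_hidden = n_hidden
        self.split = split
        self.patience = patience
        self.max_epochs = max_epochs
        self.mse_goal = mse_goal
        self.seed = seed

    def fit(self, X, Y):
        X = np.atleast_2d(np.asarray(X, float))
        Y = np.atleast_2d(np.asarray(Y, float))
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        net = init_network(self.seed, n_input=X.shape[1], n_hidden=self.n_hidden,
                           n_output=Y.shape[1])
        net, hist = train_lm(net, X - self.x_mean_, Y - self.y_mean_,
                             split=self.split, patience=self.patience,
                             max_epochs=self.max_epochs, mse_goal=self.mse_goal)
        net.x_mean = self.x_mean_
        net.y_mean = self.y_mean_
        self.network_ = net
        self.history_ = hist
        return self

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return ann_predict(self.network_, X - self.x_mean_)
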