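"""Three small regression networks sharing one Gaussian kernel.

All three families map a 4-dimensional encoded factor vector (melatonin
dose, day, species code, % field capacity), normalized to [-1, 1], to one
scalar response:

* :class:`GRNNModel` — a generalized regression neural network, i.e. a
  Nadaraya–Watson kernel smoother whose "pattern neurons" are the training
  points themselves.  Its only hyperparameter is the kernel spread ``h``.
* :class:`RBFModel` — a radial basis function network with one Gaussian
  unit per training point plus a bias; the linear output weights are the
  (optionally ridge-regularized) least-squares solution.
* :class:`MLPModel` — a single-hidden-layer perceptron with logistic
  hidden units and a linear output, trained by full-batch L-BFGS from a
  seeded random initialization with restarts.

The kernel carries the conventional 0.8326 factor (≈ sqrt(ln 2)), which
makes it equal exactly 0.5 at distance ``h`` — ``h`` is the kernel's
half-width rather than a standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

HALF_WIDTH_FACTOR = 0.8326  # ~= sqrt(ln 2): kernel value 0.5 at distance h

__all__ = [
    "HALF_WIDTH_FACTOR",
    "gaussian_kernel",
    "GRNNModel",
    "grnn_fit",
    "grnn_predict",
    "select_spread",
    "RBFModel",
    "rbf_fit",
    "rbf_predict",
    "select_rbf_spread",
    "MLPModel",
    "MLPConfig",
    "mlp_fit",
    "mlp_predict",
    "choose_hidden_neurons",
]


def _check_spread(h: float) -> float:
    h = float(h)
    if not h > 0:
        raise ValueError(f"kernel spread h must be positive, got {h}")
    return h


def gaussian_kernel(x_r: np.ndarray, x_b: np.ndarray, h: float) -> float:
    """Gaussian half-width kernel exp(-(||x_r - x_b|| * 0.8326 / h)^2)."""
    h = _check_spread(h)
    d = np.linalg.norm(np.asarray(x_r, float) - np.asarray(x_b, float))
    return float(np.exp(-((d * HALF_WIDTH_FACTOR / h) ** 2)))


def _log_kernel_matrix(Xq: np.ndarray, Xb: np.ndarray, h: float) -> np.ndarray:
    """Log-kernel between query rows and basis rows (n_q x m)."""
    d2 = np.sum((Xq[:, None, :] - Xb[None, :, :]) ** 2, axis=2)
    return -d2 * (HALF_WIDTH_FACTOR / h) ** 2


@dataclass
class GRNNModel:
    """Lazy kernel regressor: stores the training set and a spread ``h``.

    Predictions are kernel-weighted means of the training targets, hence
    always lie inside [min(T), max(T)].
    """

    X: np.ndarray
    T: np.ndarray
    h: float

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, float))
        self.T = np.asarray(self.T, float).ravel()
        if len(self.X) != len(self.T):
            raise ValueError("X and T length mismatch")
        if len(self.T) < 1:
            raise ValueError("GRNN needs at least one training point")
        self.h = _check_spread(self.h)

    def predict(self, Xq: np.ndarray) -> np.ndarray:
        """Vectorized prediction for a batch of query rows."""
        Xq = np.atleast_2d(np.asarray(Xq, float))
        logk = _log_kernel_matrix(Xq, self.X, self.h)
        # max-shift: the largest kernel per query becomes exp(0)=1, so the
        # denominator can never underflow to zero.
        shift = logk.max(axis=1, keepdims=True)
        finite = np.isfinite(shift).ravel()
        out = np.empty(len(Xq))
        if finite.any():
            k = np.exp(logk[finite] - shift[finite])
            out[finite] = k @ self.T / k.sum(axis=1)
        if not finite.all():
            warnings.warn(
                "GRNN kernel weights underflowed for some queries; "
                "falling back to nearest-neighbour targets",
                RuntimeWarning,
            )
            bad = ~finite
            d2 = np.sum((Xq[bad, None, :] - self.X[None, :, :]) ** 2, axis=2)
            out[bad] = self.T[np.argmin(d2, axis=1)]
        return out

    def to_dict(self) -> dict:
        return {
            "family": "grnn",
            "h": self.h,
            "X": self.X.tolist(),
            "T": self.T.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GRNNModel":
        return cls(np.array(d["X"]), np.array(d["T"]), d["h"])


def grnn_fit(X: np.ndarray, T: np.ndarray, h: float) -> GRNNModel:
    """'Training' a GRNN is storage: one pattern neuron per observation."""
    return GRNNModel(X, T, h)


def grnn_predict(model: GRNNModel, x_r: np.ndarray) -> float:
    """Scalar convenience wrapper around :meth:`GRNNModel.predict`."""
    return float(model.predict(np.atleast_2d(x_r))[0])


def _grnn_loo_rmse(X: np.ndarray, T: np.ndarray, h: float) -> float:
    """Leave-one-out RMSE of a GRNN — cheap because the learner is lazy."""
    logk = _log_kernel_matrix(X, X, h)
    np.fill_diagonal(logk, -np.inf)
    shift = logk.max(axis=1, keepdims=True)
    shift[~np.isfinite(shift)] = 0.0
    k = np.exp(logk - shift)
    denom = k.sum(axis=1)
    pred = np.empty(len(T))
    ok = denom > 0
    pred[ok] = (k @ T)[ok] / denom[ok]
    if not ok.all():
        # all other kernels underflowed: nearest-neighbour fallback
        bad = np.nonzero(~ok)[0]
        d2 = np.sum((X[bad, None, :] - X[None, :, :]) ** 2, axis=2)
        for r, i in enumerate(bad):
            d2[r, i] = np.inf  # exclude the held-out point itself
        pred[bad] = T[np.argmin(d2, axis=1)]
    return float(np.sqrt(np.mean((T - pred) ** 2)))


DEFAULT_SPREAD_GRID: np.ndarray = np.geomspace(0.05, 4.0, 40)


def select_spread(
    X: np.ndarray,
    T: np.ndarray,
    candidate_grid: np.ndarray | None = None,
    cv_folds: int | None = None,
    seed: int = 0,
) -> float:
    """Pick the GRNN spread minimizing leave-one-out RMSE over a grid.

    Ties are broken toward the larger (smoother) spread.  ``cv_folds`` and
    ``seed`` are accepted for interface symmetry with the RBF selector; the
    GRNN uses exact leave-one-out, which is deterministic.
    """
    grid = DEFAULT_SPREAD_GRID if candidate_grid is None else np.asarray(candidate_grid, float)
    if grid.size == 0:
        raise ValueError("empty spread candidate grid")
    X = np.atleast_2d(np.asarray(X, float))
    T = np.asarray(T, float).ravel()
    best_h, best_rmse = None, np.inf
    for h in np.sort(grid):
        r = _grnn_loo_rmse(X, T, _check_spread(h))
        if r <= best_rmse:  # <=: prefer the larger h on ties
            best_h, best_rmse = float(h), r
    return best_h


@dataclass
class RBFModel:
    """Radial basis function network with centers at the training points."""

    centers: np.ndarray
    h: float
    weights: np.ndarray
    bias: float

    def predict(self, Xq: np.ndarray) -> np.ndarray:
        Xq = np.atleast_2d(np.asarray(Xq, float))
        phi = np.exp(_log_kernel_matrix(Xq, self.centers, self.h))
        return phi @ self.weights + self.bias

    def to_dict(self) -> dict:
        return {
            "family": "rbf",
            "h": self.h,
            "centers": self.centers.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RBFModel":
        return cls(np.array(d["centers"]), d["h"], np.array(d["weights"]), d["bias"])


def rbf_fit(X: np.ndarray, T: np.ndarray, h: float, ridge: float = 1e-8) -> RBFModel:
    """Fit output weights by (ridge) least squares on the kernel design.

    The bias absorbs the target mean; the weights solve
    (Phi'Phi + ridge I) w = Phi'(T - mean(T)), so ridge=0 on distinct
    points gives exact interpolation and a constant target gives w = 0.
    """
    h = _check_spread(h)
    X = np.atleast_2d(np.asarray(X, float))
    T = np.asarray(T, float).ravel()
    phi = np.exp(_log_kernel_matrix(X, X, h))
    bias = float(T.mean())
    resid = T - bias
    m = len(T)
    A = phi.T @ phi + ridge * np.eye(m)
    b = phi.T @ resid
    try:
        w = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as e:
        if ridge == 0:
            raise np.linalg.LinAlgError(
                "singular RBF kernel system (duplicate or near-duplicate "
                "training points); refit with a nonzero ridge"
            ) from e
        raise
    if ridge == 0 and not np.allclose(phi @ w, resid, atol=1e-5 * (1 + np.abs(resid).max())):
        raise np.linalg.LinAlgError(
            "RBF kernel system numerically singular at ridge=0; "
            "refit with a nonzero ridge"
        )
    return RBFModel(X, h, w, bias)


def rbf_predict(model: RBFModel, x_r: np.ndarray) -> float:
    return float(model.predict(np.atleast_2d(x_r))[0])


def select_rbf_spread(
    X: np.ndarray,
    T: np.ndarray,
    candidate_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    ridge: float = 1e-8,
) -> float:
    """Pick the RBF spread by seeded k-fold cross-validated RMSE.

    Unlike the GRNN, the RBF refits its linear system per fold, so k-fold
    (default 5) is used instead of exact leave-one-out.  Ties break toward
    the larger spread.
    """
    grid = DEFAULT_SPREAD_GRID if candidate_grid is None else np.asarray(candidate_grid, float)
    if grid.size == 0:
        raise ValueError("empty spread candidate grid")
    X = np.atleast_2d(np.asarray(X, float))
    T = np.asarray(T, float).ravel()
    n = len(T)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, cv_folds)
    best_h, best_rmse = None, np.inf
    for h in np.sort(grid):
        sse, cnt = 0.0, 0
        for fold in folds:
            mask = np.ones(n, bool)
            mask[fold] = False
            if mask.sum() < 2:
                continue
            model = rbf_fit(X[mask], T[mask], h, ridge=ridge)
            err = T[fold] - model.predict(X[fold])
            sse += float(err @ err)
            cnt += len(fold)
        r = np.sqrt(sse / cnt)
        if r <= best_rmse:
            best_h, best_rmse = float(h), r
    return best_h


# ---------------------------------------------------------------------------
# MLP


@dataclass
class MLPConfig:
    """Training budget for the single-hidden-layer perceptron."""

    max_iter: int = 500
    n_restarts: int = 2
    init_scale: float = 0.5
    weight_decay: float = 1e-4


@dataclass
class MLPModel:
    """y = w0 + sum_j w_j * sigmoid(W_ji x + b_j); weights from L-BFGS."""

    W_hidden: np.ndarray  # m x n
    b_hidden: np.ndarray  # m
    w_out: np.ndarray  # m
    b_out: float
    loss_history: list = field(default_factory=list, repr=False)

    @property
    def m_hidden(self) -> int:
        return len(self.b_hidden)

    def predict(self, Xq: np.ndarray) -> np.ndarray:
        Xq = np.atleast_2d(np.asarray(Xq, float))
        H = expit(Xq @ self.W_hidden.T + self.b_hidden)
        return H @ self.w_out + self.b_out

    def to_dict(self) -> dict:
        return {
            "family": "mlp",
            "W_hidden": self.W_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        return cls(
            np.array(d["W_hidden"]),
            np.array(d["b_hidden"]),
            np.array(d["w_out"]),
            d["b_out"],
        )


def _unpack(theta: np.ndarray, n: int, m: int):
    i = 0
    W = theta[i : i + m * n].reshape(m, n); i += m * n
    bh = theta[i : i + m]; i += m
    wo = theta[i : i + m]; i += m
    bo = theta[i]
    return W, bh, wo, bo


def _mlp_loss_grad(theta: np.ndarray, X: np.ndarray, T: np.ndarray, m: int, decay: float):
    n = X.shape[1]
    W, bh, wo, bo = _unpack(theta, n, m)
    H = expit(X @ W.T + bh)  # N x m
    pred = H @ wo + bo
    err = pred - T
    N = len(T)
    loss = float(err @ err) / N + decay * float(theta[:-1] @ theta[:-1])
    # backprop
    g_pred = 2.0 * err / N
    g_wo = H.T @ g_pred
    g_bo = g_pred.sum()
    g_H = np.outer(g_pred, wo)
    g_A = g_H * H * (1 - H)
    g_W = g_A.T @ X
    g_bh = g_A.sum(axis=0)
    grad = np.concatenate([g_W.ravel(), g_bh, g_wo, [g_bo]])
    grad[:-1] += 2 * decay * theta[:-1]
    return loss, grad


def mlp_fit(
    X: np.ndarray,
    T: np.ndarray,
    m_hidden: int,
    config: MLPConfig | None = None,
    seed: int = 0,
    _max_total_restarts: int = 10,
) -> MLPModel:
    """Train by full-batch L-BFGS from seeded random starts; keep the best.

    Restarts with a fresh derived seed on a non-finite loss; fails after
    ``_max_total_restarts`` consecutive non-finite attempts.
    """
    if m_hidden < 1:
        raise ValueError("m_hidden must be >= 1")
    config = config or MLPConfig()
    X = np.atleast_2d(np.asarray(X, float))
    T = np.asarray(T, float).ravel()
    n = X.shape[1]
    n_params = m_hidden * n + 2 * m_hidden + 1
    rng = np.random.default_rng(seed)

    best = None
    best_loss = np.inf
    attempts = 0
    successes = 0
    while successes < config.n_restarts:
        if attempts >= config.n_restarts + _max_total_restarts:
            if best is None:
                raise RuntimeError(
                    "MLP training produced non-finite losses in every restart"
                )
            break
        attempts += 1
        theta0 = rng.normal(0.0, config.init_scale, n_params)
        history: list[float] = []

        def cb(theta, _hist=history):
            _hist.append(_mlp_loss_grad(theta, X, T, m_hidden, config.weight_decay)[0])

        res = minimize(
            _mlp_loss_grad,
            theta0,
            args=(X, T, m_hidden, config.weight_decay),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": config.max_iter},
            callback=cb,
        )
        if not np.isfinite(res.fun):
            continue
        successes += 1
        if res.fun < best_loss:
            best_loss = res.fun
            W, bh, wo, bo = _unpack(res.x, n, m_hidden)
            best = MLPModel(W.copy(), bh.copy(), wo.copy(), float(bo), history)
    return best


def mlp_predict(model: MLPModel, x_r: np.ndarray) -> float:
    return float(model.predict(np.atleast_2d(x_r))[0])


def choose_hidden_neurons(n_inputs: int, n_data: int) -> list[int]:
    """Candidate hidden-layer sizes: n, 2n, ceil(log10 K), plus midpoints.

    These are the standard starting heuristics for a single hidden layer;
    the final size is picked by validation RMSE over this list.
    """
    if n_inputs < 1 or n_data < 2:
        raise ValueError("need n_inputs >= 1 and n_data >= 2")
    cands = {
        n_inputs,
        2 * n_inputs,
        max(1, int(np.ceil(np.log10(n_data)))),
    }
    cands.add(max(1, round(1.5 * n_inputs)))  # midpoint between n and 2n
    return sorted(cands)


def select_mlp(
    X: np.ndarray,
    T: np.ndarray,
    candidates: list[int] | None = None,
    config: MLPConfig | None = None,
    seed: int = 0,
    val_fraction: float = 0.25,
) -> MLPModel:
    """Architecture search: hold out part of the training rows, pick the
    hidden-layer size with the lowest validation RMSE, then refit on all rows."""
    X = np.atleast_2d(np.asarray(X, float))
    T = np.asarray(T, float).ravel()
    if candidates is None:
        candidates = choose_hidden_neurons(X.shape[1], len(T))
    if len(candidates) == 1:
        return mlp_fit(X, T, candidates[0], config, seed)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(T))
    n_val = max(1, int(round(val_fraction * len(T))))
    val, tr = perm[:n_val], perm[n_val:]
    best_m, best_rmse = candidates[0], np.inf
    for k, m in enumerate(sorted(candidates)):
        model = mlp_fit(X[tr], T[tr], m, config, seed + 1000 * (k + 1))
        r = float(np.sqrt(np.mean((T[val] - model.predict(X[val])) ** 2)))
        if r < best_rmse:
            best_m, best_rmse = m, r
    return mlp_fit(X, T, best_m, config, seed)
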