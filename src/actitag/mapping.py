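"""Supervised subspace mappings used inside each dichotomy node.

Two linear mappings are provided:

* **Maximally collapsing metric (MCM).**  A rank-d Mahalanobis factor A
  (Sigma = A^T A) is learned by minimizing the KL divergence between a
  bi-level target neighbour distribution p0(j|i) — 1 for same-class pairs,
  0 otherwise, row-normalized — and the model distribution
  p_hat(j|i) = exp(-d_ij) / sum_{q != i} exp(-d_iq) with
  d_ij = (x_i - x_j)^T A^T A (x_i - x_j).  Collapsing same-class
  neighbourhoods maximizes class separability in the mapped space.
  Optimized by gradient descent with backtracking line search.

* **Discriminative autoencoder (DAUT).**  An all-linear encoder H (d x m)
  jointly minimizing reconstruction and classification error,

      min_{W1, W2, H}  ||X - W1 H X||^2 + lambda ||Y - W2 H X||^2,

  with Y one-hot labels.  Solved by exact alternating least squares: W1,
  W2 and H each have closed-form normal-equation updates, so the objective
  is monotonically non-increasing.  lambda can be chosen by the L-curve
  corner (maximum curvature of log reconstruction error vs log
  classification error over a logarithmic grid).

Mapped samples are the matrix product of the input with the encoding
matrix (A or H).  Both fits are deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger(__name__)

__all__ = [
    "MetricMapping",
    "AutoencoderMapping",
    "fit_mcm",
    "fit_daut",
    "lcurve_corner",
    "transform",
]


@dataclass
class MetricMapping:
    """Learned Mahalanobis factor A (d x m); Sigma = A^T A is PSD by construction."""

    A: np.ndarray
    objective: float
    n_iter: int
    #: objective value after each accepted iteration (non-increasing)
    trace: "list[float] | None" = field(default=None, repr=False)

    @property
    def encoding(self) -> np.ndarray:
        return self.A


@dataclass
class AutoencoderMapping:
    """Linear discriminative autoencoder weights.

    ``H`` (d x m) encodes, ``W1`` (m x d) reconstructs, ``W2`` (C x d)
    classifies; ``lam`` weights the classification term.
    """

    H: np.ndarray
    W1: np.ndarray
    W2: np.ndarray
    lam: float
    objective: float
    n_iter: int
    lcurve: "list[tuple[float, float, float]] | None" = field(default=None, repr=False)
    #: objective value after each alternating update (non-increasing)
    trace: "list[float] | None" = field(default=None, repr=False)

    @property
    def encoding(self) -> np.ndarray:
        return self.H


# ---------------------------------------------------------------------------
# MCM
# ---------------------------------------------------------------------------

def _mcm_objective_grad(A: np.ndarray, X: np.ndarray, P0: np.ndarray):
    """KL(p0 || p_hat) summed over rows, and its gradient w.r.t. A."""
    Z = X @ A.T
    D = squareform(pdist(Z, "sqeuclidean"))
    np.fill_diagonal(D, np.inf)  # exclude j == i
    # log-sum-exp stabilised model distribution
    neg = -D
    mx = neg.max(axis=1, keepdims=True)
    E = np.exp(neg - mx)
    S = E.sum(axis=1, keepdims=True)
    logp = neg - mx - np.log(S)
    Phat = E / S
    mask = P0 > 0
    # true KL(p0 || p_hat): cross-entropy plus the (A-independent) entropy term
    obj = float((P0[mask] * (np.log(P0[mask]) - logp[mask])).sum())
    # dObj/dA = 2 A * sum_ij (P0 - Phat)_ij (x_i - x_j)(x_i - x_j)^T
    W = P0 - Phat
    W = W + W.T  # symmetrize pair contributions
    lap = np.diag(W.sum(axis=1)) - W  # graph Laplacian form
    grad = 2.0 * A @ (X.T @ lap @ X)
    return obj, grad


def fit_mcm(
    X: np.ndarray,
    y: np.ndarray,
    d: int,
    max_iter: int = 100,
    tol: float = 1e-5,
    rng_seed: int = 0,
) -> MetricMapping:
    """Fit the maximally collapsing metric by first-order descent.

    A is initialized from a seeded Gaussian scaled by 1/sqrt(m); steps use
    backtracking line search, so the objective is non-increasing across
    accepted iterations.  Stops when the relative objective decrease falls
    below ``tol`` or the line search stalls.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, m = X.shape
    if d > m:
        raise ValueError("target dimension d must be <= number of descriptors")
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        raise ValueError("fit_mcm needs at least 2 samples per class")
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    P0 = same / same.sum(axis=1, keepdims=True)

    rng = np.random.default_rng(rng_seed)
    A = rng.normal(0.0, 1.0 / np.sqrt(m), size=(d, m))
    obj, grad = _mcm_objective_grad(A, X, P0)
    if not np.isfinite(obj):
        raise FloatingPointError("non-finite MCM objective at initialization")
    step = 1.0 / max(1.0, np.linalg.norm(grad))
    trace = [obj]
    it = 0
    for it in range(1, max_iter + 1):
        accepted = False
        for _ in range(30):  # backtracking
            A_new = A - step * grad
            obj_new, grad_new = _mcm_objective_grad(A_new, X, P0)
            if np.isfinite(obj_new) and obj_new <= obj:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        rel = (obj - obj_new) / max(abs(obj), 1e-12)
        A, obj, grad = A_new, obj_new, grad_new
        trace.append(obj)
        step *= 1.2
        if rel < tol:
            break
    if not np.isfinite(obj):
        raise FloatingPointError("non-finite MCM objective during optimization")
    return MetricMapping(A=A, objective=obj, n_iter=it, trace=trace)


# ---------------------------------------------------------------------------
# DAUT
# ---------------------------------------------------------------------------

def _solve_ridge(G: np.ndarray, B: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Solve G @ out = B with a tiny ridge for rank-deficient G."""
    G = G + eps * np.eye(G.shape[0])
    return np.linalg.solve(G, B)


def _daut_objective(X, Y, H, W1, W2, lam) -> float:
    Z = X @ H.T
    rec = np.linalg.norm(X - Z @ W1.T) ** 2
    cls = np.linalg.norm(Y - Z @ W2.T) ** 2
    return float(rec + lam * cls)


def _fit_daut_fixed_lambda(X, Y, d, lam, max_iter, tol):
    n, m = X.shape
    # deterministic init: encoder spanning the top-d right singular subspace
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    H = Vt[:d]
    obj = np.inf
    trace = []
    it = 0
    for it in range(1, max_iter + 1):
        Z = X @ H.T
        G = Z.T @ Z
        W1 = _solve_ridge(G, Z.T @ X).T
        W2 = _solve_ridge(G, Z.T @ Y).T
        # closed form for H given (W1, W2):
        #   (X^T X) H^T (W1^T W1 + lam W2^T W2) = X^T (X W1 + lam Y W2)
        M = W1.T @ W1 + lam * (W2.T @ W2)
        B = X.T @ (X @ W1 + lam * (Y @ W2))
        G = _solve_ridge(X.T @ X, B) @ np.linalg.inv(M + 1e-12 * np.eye(d))
        H = G.T
        obj_new = _daut_objective(X, Y, H, W1, W2, lam)
        done = obj - obj_new < tol * max(abs(obj_new), 1e-12)
        obj = obj_new
        trace.append(obj)
        if done:
            break
    Z = X @ H.T
    G = Z.T @ Z
    W1 = _solve_ridge(G, Z.T @ X).T
    W2 = _solve_ridge(G, Z.T @ Y).T
    obj = _daut_objective(X, Y, H, W1, W2, lam)
    trace.append(obj)
    rec = float(np.linalg.norm(X - Z @ W1.T) ** 2)
    cls = float(np.linalg.norm(Y - Z @ W2.T) ** 2)
    return H, W1, W2, obj, it, rec, cls, trace


def lcurve_corner(points: "list[tuple[float, float, float]]") -> float:
    """Pick lambda at the maximum-curvature corner of the L-curve.

    ``points`` are (lambda, reconstruction error, classification error);
    curvature is evaluated on (log rec, log cls) by central differences.
    """
    lams = np.array([p[0] for p in points])
    xs = np.log(np.maximum([p[1] for p in points], 1e-300))
    ys = np.log(np.maximum([p[2] for p in points], 1e-300))
    t = np.log(lams)
    dx, dy = np.gradient(xs, t), np.gradient(ys, t)
    ddx, ddy = np.gradient(dx, t), np.gradient(dy, t)
    denom = (dx**2 + dy**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.abs(dx * ddy - dy * ddx) / denom
    kappa[~np.isfinite(kappa)] = -np.inf
    return float(lams[int(np.argmax(kappa))])


def fit_daut(
    X: np.ndarray,
    Y_onehot: np.ndarray,
    d: int,
    lam: "float | str" = 1.0,
    max_iter: int = 200,
    tol: float = 1e-10,
    rng_seed: int = 0,
) -> AutoencoderMapping:
    """Fit the linear discriminative autoencoder.

    ``lam="lcurve"`` selects lambda at the L-curve corner over a 25-point
    logarithmic grid in [1e-4, 1e4].  The fit itself is deterministic (SVD
    initialization); ``rng_seed`` is accepted for interface uniformity.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y_onehot, dtype=float)
    if Y.ndim != 2:
        raise ValueError("labels must be one-hot encoded (n x C)")
    n, m = X.shape
    if d > m:
        raise ValueError("target dimension d must be <= number of descriptors")
    if np.linalg.matrix_rank(X) < min(n, m):
        logger.info("fit_daut: rank-deficient X, using 1e-8 ridge")

    curve = None
    if isinstance(lam, str):
        if lam != "lcurve":
            raise ValueError(f"lam must be a float or 'lcurve', got {lam!r}")
        curve = []
        for lam_i in np.logspace(-4, 4, 25):
            *_, rec, cls, _ = _fit_daut_fixed_lambda(X, Y, d, lam_i, max_iter=50, tol=tol)
            curve.append((float(lam_i), rec, cls))
        lam = lcurve_corner(curve)
    H, W1, W2, obj, it, _, _, trace = _fit_daut_fixed_lambda(X, Y, d, float(lam), max_iter, tol)
    return AutoencoderMapping(
        H=H, W1=W1, W2=W2, lam=float(lam), objective=obj, n_iter=it, lcurve=curve,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# Transform
# ---------------------------------------------------------------------------

def transform(X: np.ndarray, mapping: "MetricMapping | AutoencoderMapping") -> np.ndarray:
    """Map samples into the learned subspace: rows of X times A^T (or H^T)."""
    X = np.asarray(X, dtype=float)
    E = mapping.encoding
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != E.shape[1]:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[1]} columns, mapping expects {E.shape[1]}"
        )
    return X @ E.T
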