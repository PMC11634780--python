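"""Batched L2-regularized logistic regression.

Fits many small binary logistic problems at once (one per decoding timepoint
and held-out trial) by damped Newton iterations vectorized over a leading
batch axis. The ridge penalty (weak, fixed) guarantees a bounded optimum
even on separable folds; the intercept is unpenalized.

When the sample count is below the feature count — the usual case for
leave-one-trial-out decoding of a large population — the Newton step is
taken in the sample (dual) space: by the representer property of the L2
penalty the optimal weight vector lies in the span of the training rows,
``w = X^T a``, so each Newton system is (n + 1) x (n + 1) instead of
(d + 1) x (d + 1). Small systems are solved by a Cholesky factorization
vectorized across the batch, avoiding per-matrix LAPACK dispatch overhead.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

#: probability clipping bound applied before any likelihood use
CLIP = 1e-4


def _chol_solve_batched(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve SPD systems A x = b, A: (..., m, m), b: (..., m).

    Hand-vectorized Cholesky; falls back to LAPACK for larger m where BLAS
    flops beat broadcasting.
    """
    m = A.shape[-1]
    if m > 14:  # LAPACK beats broadcasting once systems are this large
        return np.linalg.solve(A, b[..., None])[..., 0]
    L = np.zeros_like(A)
    A = A.copy()
    for k in range(m):
        L[..., k, k] = np.sqrt(A[..., k, k])
        if k + 1 < m:
            L[..., k + 1:, k] = A[..., k + 1:, k] / L[..., k, k][..., None]
            A[..., k + 1:, k + 1:] -= (L[..., k + 1:, k][..., :, None]
                                       * L[..., k + 1:, k][..., None, :])
    # forward substitution L z = b
    z = np.zeros_like(b)
    for k in range(m):
        s = np.einsum("...j,...j->...", L[..., k, :k], z[..., :k]) if k else 0.0
        z[..., k] = (b[..., k] - s) / L[..., k, k]
    # back substitution L^T x = z
    x = np.zeros_like(b)
    for k in range(m - 1, -1, -1):
        s = (np.einsum("...j,...j->...", L[..., k + 1:, k], x[..., k + 1:])
             if k + 1 < m else 0.0)
        x[..., k] = (z[..., k] - s) / L[..., k, k]
    return x


def _newton(z_of, grad_hess, theta0, objective, n_iter, tol, n_scale):
    """Generic damped Newton loop shared by primal and dual paths."""
    theta = theta0
    f = objective(theta)
    for _ in range(n_iter):
        g, H = grad_hess(theta)
        if np.abs(g).max() < tol * n_scale:
            break
        step = _chol_solve_batched(H, g)
        t = np.ones(theta.shape[:-1])
        new = theta - step
        fn = objective(new)
        for _ in range(20):  # halve the step wherever the objective worsens
            bad = fn > f + 1e-12
            if not np.any(bad):
                break
            t = np.where(bad, t * 0.5, t)
            new = theta - t[..., None] * step
            fn = np.where(bad, objective(new), fn)
        theta, f = new, fn
    return theta


def fit_ridge_logistic(X: np.ndarray, y: np.ndarray, lam: float = 1.0,
                       n_iter: int = 25, tol: float = 1e-5) -> np.ndarray:
    """Fit ``sigma(X w + b)`` to binary targets with an L2 penalty on ``w``.

    Parameters
    ----------
    X : (..., n, d) design without intercept column.
    y : (..., n) targets in {0, 1}; broadcast over batch dims if 1-D.
    lam : ridge strength on the non-intercept coefficients.

    Returns
    -------
    beta : (..., d + 1) with the intercept last.
    """
    X = np.asarray(X, dtype=np.float64)
    batch = X.shape[:-2]
    n, d = X.shape[-2:]
    y = np.broadcast_to(np.asarray(y, dtype=np.float64), batch + (n,))
    if len(batch) > 1:  # flatten to one batch axis: faster einsum dispatch
        Xf = np.ascontiguousarray(X.reshape((-1, n, d)))
        yf = np.ascontiguousarray(y.reshape((-1, n)))
        out = fit_ridge_logistic(Xf, yf, lam=lam, n_iter=n_iter, tol=tol)
        return out.reshape(batch + (d + 1,))
    if n < d:
        return _fit_dual(X, y, lam, n_iter, tol)
    return _fit_primal(X, y, lam, n_iter, tol)


def _fit_primal(X, y, lam, n_iter, tol):
    batch = X.shape[:-2]
    n, d = X.shape[-2:]
    X1 = np.concatenate([X, np.ones(batch + (n, 1))], axis=-1)
    pen = np.full(d + 1, lam)
    pen[-1] = 0.0

    def objective(b):
        z = np.einsum("...ni,...i->...n", X1, b)
        nll = np.logaddexp(0.0, z).sum(-1) - (y * z).sum(-1)
        return nll + 0.5 * (pen * b * b).sum(-1)

    diag = np.arange(d + 1)

    def grad_hess(b):
        z = np.einsum("...ni,...i->...n", X1, b)
        p = expit(z)
        g = np.einsum("...ni,...n->...i", X1, p - y) + pen * b
        w = p * (1.0 - p)
        H = np.einsum("...ni,...n,...nj->...ij", X1, w, X1, optimize=True)
        H[..., diag, diag] += pen
        return g, H

    beta0 = np.zeros(batch + (d + 1,))
    return _newton(None, grad_hess, beta0, objective, n_iter, tol, max(n, 1))


def _fit_dual(X, y, lam, n_iter, tol):
    """Newton in (a, b) with w = X^T a; returns the primal beta."""
    batch = X.shape[:-2]
    n, d = X.shape[-2:]
    K = np.einsum("...ni,...mi->...nm", X, X, optimize=True)
    # tiny jitter keeps K PD when rows are linearly dependent
    eps = 1e-9 * (np.einsum("...ii->...", K)[..., None, None] / n + 1.0)
    K = K + eps * np.eye(n)

    def split(th):
        return th[..., :n], th[..., n]

    def objective(th):
        a, b = split(th)
        Ka = np.einsum("...nm,...m->...n", K, a)
        z = Ka + b[..., None]
        nll = np.logaddexp(0.0, z).sum(-1) - (y * z).sum(-1)
        return nll + 0.5 * lam * (a * Ka).sum(-1)

    def grad_hess(th):
        a, b = split(th)
        Ka = np.einsum("...nm,...m->...n", K, a)
        z = Ka + b[..., None]
        p = expit(z)
        u = p - y + lam * a
        g = np.empty(th.shape)
        g[..., :n] = np.einsum("...nm,...m->...n", K, u)
        g[..., n] = (p - y).sum(-1)
        w = p * (1.0 - p)
        KS = K * w[..., None, :]
        H = np.empty(th.shape + (n + 1,))
        H[..., :n, :n] = (np.einsum("...nm,...mk->...nk", KS, K,
                                    optimize=True) + lam * K)
        KSo = KS.sum(-1)
        H[..., :n, n] = KSo
        H[..., n, :n] = KSo
        H[..., n, n] = w.sum(-1)
        return g, H

    th0 = np.zeros(batch + (n + 1,))
    th = _newton(None, grad_hess, th0, objective, n_iter, tol, max(n, 1))
    a, b = split(th)
    beta = np.empty(batch + (d + 1,))
    beta[..., :d] = np.einsum("...nd,...n->...d", X, a)
    beta[..., d] = b
    return beta


def predict_proba(beta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """P(y = 1) for features ``x`` (..., d) under fits ``beta`` (..., d + 1)."""
    z = np.einsum("...i,...i->...", x, beta[..., :-1]) + beta[..., -1]
    return np.clip(expit(z), CLIP, 1.0 - CLIP)
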