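"""Numba block coordinate descent solver for the graphical lasso.

Solves, for a symmetric input matrix ``S`` (here always a correlation
matrix) and penalty ``lam >= 0``::

    maximize  log det(Theta) - trace(S Theta) - lam * sum_{i != j} |Theta_ij|

over symmetric positive-definite ``Theta``.  The penalty is applied to
off-diagonal entries only, so the diagonal of the covariance estimate W
equals the diagonal of S.  The algorithm is the classic column-wise block
coordinate descent: each column of W is updated by solving a lasso
subproblem with cyclic coordinate descent, warm-started from the previous
state, which makes descending-lambda paths cheap.

Convergence follows the usual glasso criterion: the sweep stops when the
largest change of any W entry falls below ``tol`` times the mean absolute
off-diagonal of S.  Coordinate-descent soft-thresholding yields exact
zeros in Theta, so edge counts need no post-hoc thresholding at this
level.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["glasso_single", "glasso_path"]


@njit(cache=True)
def _cd_sweep(S, lam, W, B, thr, max_iter):
    """One full glasso solve, in place. Returns (n_iter, converged)."""
    p = S.shape[0]
    for j in range(p):
        W[j, j] = S[j, j]
    n_iter = 0
    converged = False
    for it in range(max_iter):
        n_iter = it + 1
        max_delta = 0.0
        for j in range(p):
            # lasso subproblem for column j: cyclic coordinate descent on beta
            for _ in range(1000):
                d_in = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    r = S[k, j]
                    for l in range(p):
                        if l != j and l != k:
                            r -= W[k, l] * B[j, l]
                    b_old = B[j, k]
                    if r > lam:
                        b_new = (r - lam) / W[k, k]
                    elif r < -lam:
                        b_new = (r + lam) / W[k, k]
                    else:
                        b_new = 0.0
                    B[j, k] = b_new
                    d = abs(b_new - b_old)
                    if d > d_in:
                        d_in = d
                if d_in < 0.1 * thr:
                    break
            # propagate: w_12 = W_11 beta
            for k in range(p):
                if k == j:
                    continue
                w = 0.0
                for l in range(p):
                    if l != j:
                        w += W[k, l] * B[j, l]
                d = abs(w - W[k, j])
                if d > max_delta:
                    max_delta = d
                W[k, j] = w
                W[j, k] = w
        if max_delta < thr:
            converged = True
            break
    return n_iter, converged


@njit(cache=True)
def _theta_from_wb(W, B):
    """Recover Theta from the covariance estimate and regression coefs."""
    p = W.shape[0]
    T = np.zeros((p, p))
    for j in range(p):
        w12b = 0.0
        for l in range(p):
            if l != j:
                w12b += W[j, l] * B[j, l]
        tjj = 1.0 / (W[j, j] - w12b)
        T[j, j] = tjj
        for k in range(p):
            if k != j:
                T[k, j] = -B[j, k] * tjj
    # symmetrize, preserving exact zeros from soft-thresholding
    for a in range(p):
        for b in range(a + 1, p):
            if T[a, b] == 0.0 or T[b, a] == 0.0:
                v = 0.0
            else:
                v = 0.5 * (T[a, b] + T[b, a])
            T[a, b] = v
            T[b, a] = v
    return T


def _threshold(S, tol):
    off = np.abs(S - np.diag(np.diag(S)))
    p = S.shape[0]
    denom = max(p * (p - 1), 1)
    return tol * (off.sum() / denom + 1e-12)


def glasso_single(S, lam, tol=1e-4, max_iter=200, W=None, B=None):
    """Solve one glasso problem; returns (theta, n_iter, converged).

    ``W``/``B`` may carry warm-start state and are updated in place.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    p = S.shape[0]
    if W is None:
        W = S.copy()
    if B is None:
        B = np.zeros((p, p))
    n_iter, converged = _cd_sweep(S, float(lam), W, B, _threshold(S, tol), max_iter)
    return _theta_from_wb(W, B), n_iter, converged


def glasso_path(S, lambdas, tol=1e-4, max_iter=200):
    """Solve along a descending lambda path with warm starts.

    Returns (thetas, converged_flags) with ``thetas`` of shape
    ``(len(lambdas), p, p)``.
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    p = S.shape[0]
    W = S.copy()
    B = np.zeros((p, p))
    thr = _threshold(S, tol)
    thetas = np.empty((len(lambdas), p, p))
    flags = np.empty(len(lambdas), dtype=bool)
    for i, lam in enumerate(lambdas):
        _, flags[i] = _cd_sweep(S, float(lam), W, B, thr, max_iter)
        thetas[i] = _theta_from_wb(W, B)
    return thetas, flags
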