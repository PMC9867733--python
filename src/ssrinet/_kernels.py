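"""Numba-jitted inner loops of the l1 solvers.

The gaussian lasso is solved by cyclic coordinate descent on the Gram
matrix (covariance updates), so a whole regularization path costs
O(n_lambda * sweeps * p^2) independent of the sample size once
``G = X'X/n`` and ``c = X'y/n`` are formed.  The binomial lasso uses a
majorize-minimize scheme with the curvature bound 1/4: each outer step
forms a quadratic surrogate (working response) and solves it with the
same Gram coordinate descent, which is globally convergent for the
logistic loss.  The Gram matrix of the centered design is shared across
the whole binomial path.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _soft(z, t):
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@njit(cache=True)
def cd_gram(G, c, beta, lam, tol, max_sweeps):
    """Cyclic coordinate descent for (1/2) b'Gb - c'b + lam * ||b||_1.

    ``beta`` is updated in place (warm start).  Returns sweeps used.
    """
    p = beta.shape[0]
    for sweep in range(max_sweeps):
        max_change = 0.0
        for j in range(p):
            gj = G[j, j]
            if gj <= 0.0:
                beta[j] = 0.0
                continue
            r = c[j]
            for k in range(p):
                if k != j:
                    r -= G[j, k] * beta[k]
            new = _soft(r, lam) / gj
            change = abs(new - beta[j])
            if change > max_change:
                max_change = change
            beta[j] = new
        if max_change < tol:
            return sweep + 1
    return max_sweeps


@njit(cache=True)
def lasso_path_gram(G, c, grid, tol, max_sweeps):
    """Warm-started gaussian lasso path over a descending lambda grid."""
    p = c.shape[0]
    out = np.zeros((grid.shape[0], p))
    beta = np.zeros(p)
    for i in range(grid.shape[0]):
        cd_gram(G, c, beta, grid[i], tol, max_sweeps)
        out[i] = beta
    return out


@njit(cache=True)
def _centered_gram(X):
    n, p = X.shape
    xm = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j]
        xm[j] = s / n
    G = np.empty((p, p))
    for j in range(p):
        for k in range(j, p):
            s = 0.0
            for i in range(n):
                s += (X[i, j] - xm[j]) * (X[i, k] - xm[k])
            G[j, k] = s / n
            G[k, j] = G[j, k]
    return G, xm


@njit(cache=True)
def _logistic_objective(X, y, b0, beta, lam):
    n = X.shape[0]
    val = 0.0
    for i in range(n):
        eta = b0
        for j in range(X.shape[1]):
            eta += X[i, j] * beta[j]
        s = (1.0 - 2.0 * y[i]) * eta
        if s > 30.0:
            val += s
        else:
            val += np.log1p(np.exp(s))
    val /= n
    for j in range(beta.shape[0]):
        val += lam * abs(beta[j])
    return val


@njit(cache=True)
def _logistic_lasso_core(X, y, G, xm, b0, beta, lam, tol, max_outer, cd_tol, cd_sweeps):
    """MM iterations for one lambda; beta updated in place via cd_gram."""
    n, p = X.shape
    obj = _logistic_objective(X, y, b0, beta, lam)
    z = np.empty(n)
    c = np.empty(p)
    for outer in range(max_outer):
        zbar = 0.0
        for i in range(n):
            e = b0
            for j in range(p):
                e += X[i, j] * beta[j]
            mu = 1.0 / (1.0 + np.exp(-e))
            z[i] = e + 4.0 * (y[i] - mu)
            zbar += z[i]
        zbar /= n
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += (X[i, j] - xm[j]) * (z[i] - zbar)
            c[j] = s / n
        cd_gram(G, c, beta, 4.0 * lam, cd_tol, cd_sweeps)
        b0 = zbar
        for j in range(p):
            b0 -= xm[j] * beta[j]
        new_obj = _logistic_objective(X, y, b0, beta, lam)
        if abs(obj - new_obj) <= tol * max(1.0, abs(obj)):
            return b0
        obj = new_obj
    return b0


@njit(cache=True)
def logistic_lasso(X, y, b0_init, beta_init, lam, tol, max_outer, cd_tol, cd_sweeps):
    """l1-penalized logistic regression via the 1/4-bound MM scheme.

    Minimizes (1/n) sum log(1 + exp((1-2y)(b0 + x'b))) + lam ||b||_1
    with an unpenalized intercept; stops on relative objective change
    below ``tol``.
    """
    G, xm = _centered_gram(X)
    beta = beta_init.copy()
    b0 = _logistic_lasso_core(X, y, G, xm, b0_init, beta, lam, tol, max_outer,
                              cd_tol, cd_sweeps)
    return b0, beta


@njit(cache=True)
def logistic_lasso_path(X, y, grid, tol, max_outer, cd_tol, cd_sweeps):
    """Warm-started binomial lasso path over a descending lambda grid."""
    n, p = X.shape
    G, xm = _centered_gram(X)
    out_b0 = np.zeros(grid.shape[0])
    out = np.zeros((grid.shape[0], p))
    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    b0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(p)
    for g in range(grid.shape[0]):
        b0 = _logistic_lasso_core(X, y, G, xm, b0, beta, grid[g], tol, max_outer,
                                  cd_tol, cd_sweeps)
        out_b0[g] = b0
        out[g] = beta
    return out_b0, out
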