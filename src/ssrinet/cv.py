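"""Cross-validated penalty selection for nodewise regressions.

The tuning parameter of each nodewise lasso is chosen by K-fold
cross-validation (10 folds by default): the whole descending lambda path
is fitted on each training complement with warm starts, held-out loss
(mean squared error for gaussian nodes, mean deviance for the binomial
treatment node) is averaged across folds, and the loss-minimizing lambda
is selected, ties broken toward the larger (sparser) value.
"""

from __future__ import annotations

import numpy as np

from ._kernels import lasso_path_gram, logistic_lasso_path
from .solver import CD_SWEEPS, CD_TOL

#: CV path fits use slightly looser (still tight) tolerances than refits
_CV_LOGISTIC_TOL = 1e-9
_CV_LOGISTIC_MAX_OUTER = 20_000


def fold_assignments(n: int, folds: int, seed) -> np.ndarray:
    """Deterministic fold labels: a seeded permutation chunked evenly."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        labels[chunk] = f
    return labels


def _gaussian_path(X, y, grid):
    n = X.shape[0]
    xm = X.mean(axis=0)
    Xc = X - xm
    ym = y.mean()
    G = Xc.T @ Xc / n
    c = Xc.T @ (y - ym) / n
    betas = lasso_path_gram(G, c, np.asarray(grid, float), CD_TOL, CD_SWEEPS)
    b0s = ym - betas @ xm
    return b0s, betas


def _binomial_path(X, y, grid):
    return logistic_lasso_path(
        np.ascontiguousarray(X, np.float64),
        np.ascontiguousarray(y, np.float64),
        np.asarray(grid, float),
        _CV_LOGISTIC_TOL, _CV_LOGISTIC_MAX_OUTER, CD_TOL, CD_SWEEPS,
    )


def path_fit(X, y, family, grid):
    """Warm-started coefficient path over a descending grid."""
    if family == "gaussian":
        return _gaussian_path(X, y, grid)
    if family == "binomial":
        return _binomial_path(X, y, grid)
    raise ValueError(f"unknown family {family!r}")


def _held_out_loss(X, y, family, b0s, betas):
    eta = b0s[None, :] + X @ betas.T  # n_test x n_lambda
    if family == "gaussian":
        return np.mean((y[:, None] - eta) ** 2, axis=0)
    # mean binomial deviance: 2 * mean negative log-likelihood
    s = (1.0 - 2.0 * y)[:, None] * eta
    return 2.0 * np.mean(np.logaddexp(0.0, s), axis=0)


def select_lambda_cv(
    predictors: np.ndarray,
    response: np.ndarray,
    family: str = "gaussian",
    grid: np.ndarray | None = None,
    folds: int = 10,
    seed=0,
    policy: str = "min",
):
    """Select the penalty minimizing mean held-out loss.

    Returns ``(lambda_star, cv_curve)`` where ``cv_curve`` maps each grid
    lambda to its mean held-out loss.  Fold assignment is a deterministic
    function of ``seed``.  For binomial responses, folds whose training
    part has a constant response are re-drawn from a derived seed (at
    most 10 attempts) before erroring.  ``policy`` is ``"min"``
    (loss-minimizing lambda, ties toward the sparser value) or ``"1se"``
    (largest lambda within one standard error of the minimum).
    """
    if policy not in ("min", "1se"):
        raise ValueError(f"unknown lambda policy {policy!r}")
    X = np.asarray(predictors, float)
    y = np.asarray(response, float)
    n = len(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError("need at least one sample per fold")
    if grid is None:
        from .solver import lambda_grid
        grid = lambda_grid(X, y, family)
    grid = np.asarray(grid, float)

    labels = None
    for attempt in range(10):
        cand = fold_assignments(n, folds, np.random.SeedSequence([_as_int(seed), attempt]))
        if family != "binomial":
            labels = cand
            break
        ok = all(np.ptp(y[cand != f]) > 0 and np.ptp(y[cand == f]) >= 0 for f in range(folds))
        if ok:
            labels = cand
            break
    if labels is None:
        raise ValueError("could not build folds with non-constant binomial response")

    losses = np.zeros((folds, len(grid)))
    for f in range(folds):
        train = labels != f
        b0s, betas = path_fit(X[train], y[train], family, grid)
        losses[f] = _held_out_loss(X[~train], y[~train], family, b0s, betas)
    mean_loss = losses.mean(axis=0)
    if policy == "1se":
        lambda_star = select_lambda_1se(grid, mean_loss, losses)
    else:
        # grid is descending, so argmin returns the largest lambda among ties
        lambda_star = float(grid[int(np.argmin(mean_loss))])
    cv_curve = {float(l): float(v) for l, v in zip(grid, mean_loss)}
    return lambda_star, cv_curve


def select_lambda_1se(grid, cv_curve_values, fold_losses):
    """One-standard-error rule: the largest lambda whose mean loss is
    within one SE of the minimum (offered as an alternative policy)."""
    grid = np.asarray(grid, float)
    mean_loss = np.asarray(cv_curve_values, float)
    se = np.std(fold_losses, axis=0, ddof=1) / np.sqrt(fold_losses.shape[0])
    i_min = int(np.argmin(mean_loss))
    ok = mean_loss <= mean_loss[i_min] + se[i_min]
    return float(grid[int(np.flatnonzero(ok)[0])])


def _as_int(seed) -> int:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    return int(np.random.SeedSequence(seed).entropy) % (2**31)
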