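"""Nodewise l1-regularized regression: the estimation engine.

Each node of the mixed graphical model is regressed on all other nodes
with a lasso penalty: gaussian least squares for continuous (symptom)
nodes and logistic regression for the binary treatment node, both with
an unpenalized intercept.  The gaussian problem

    (1/2n) sum_i (y_i - b0 - x_i'b)^2 + lam ||b||_1

is solved exactly by coordinate descent on the Gram matrix; the
binomial problem

    (1/n) sum_i log(1 + exp((1 - 2 y_i)(b0 + x_i'b))) + lam ||b||_1

by a majorize-minimize scheme.  Every full-data fit carries a KKT
subgradient certificate (`kkt_violation`), the machine-checkable proof
that the returned coefficients minimize the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import cd_gram, logistic_lasso

#: default solver tolerances
CD_TOL = 1e-10
CD_SWEEPS = 100_000
LOGISTIC_TOL = 1e-11
LOGISTIC_MAX_OUTER = 100_000


def standardize(design: np.ndarray, kinds: list[str], names: list[str] | None = None):
    """Standardize continuous columns to mean 0 / SD 1 (denominator n-1);
    binary 0/1 columns pass through unchanged.

    Returns ``(standardized, centers, scales)``; binary columns get
    center 0 and scale 1 so the back-transformation is uniform.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be a 2-d matrix")
    n, p = X.shape
    if len(kinds) != p:
        raise ValueError("one kind per column required")
    names = names or [f"col{j}" for j in range(p)]
    out = X.copy()
    centers = np.zeros(p)
    scales = np.ones(p)
    for j, kind in enumerate(kinds):
        col = X[:, j]
        if not np.all(np.isfinite(col)):
            raise ValueError(f"non-finite values in column {names[j]!r}")
        if kind == "binary":
            if not np.isin(col, (0.0, 1.0)).all():
                raise ValueError(f"binary column {names[j]!r} is not coded 0/1")
            continue
        if kind != "continuous":
            raise ValueError(f"unknown column kind {kind!r}")
        c = col.mean()
        s = col.std(ddof=1)
        if s == 0:
            raise ValueError(f"zero-variance continuous column {names[j]!r}")
        out[:, j] = (col - c) / s
        centers[j] = c
        scales[j] = s
    return out, centers, scales


def lambda_max(predictors: np.ndarray, response: np.ndarray, family: str) -> float:
    """Smallest penalty at which all penalized coefficients are zero."""
    X = np.asarray(predictors, float)
    y = np.asarray(response, float)
    n = len(y)
    if np.ptp(y) == 0:
        raise ValueError("degenerate (constant) response")
    resid = y - y.mean()  # gaussian: y - ybar; binomial: y - pbar coincide
    if family not in ("gaussian", "binomial"):
        raise ValueError(f"unknown family {family!r}")
    return float(np.abs(X.T @ resid).max() / n)


def lambda_grid(
    predictors: np.ndarray,
    response: np.ndarray,
    family: str = "gaussian",
    n_lambda: int = 50,
    min_ratio: float = 1e-4,
) -> np.ndarray:
    """Descending log-spaced grid from lambda_max to lambda_max*min_ratio."""
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    if not 0 < min_ratio < 1:
        raise ValueError("min_ratio must lie in (0, 1)")
    lmax = lambda_max(predictors, response, family)
    return lmax * np.logspace(0, np.log10(min_ratio), n_lambda)


@dataclass
class NodewiseFit:
    """One node's penalized regression at its selected penalty."""

    node: str
    family: str
    predictors: list[str]
    intercept: float
    coefficients: np.ndarray
    lam: float
    cv_curve: dict = field(default_factory=dict)
    kkt_violation: float = float("nan")

    def coef(self, predictor: str) -> float:
        return float(self.coefficients[self.predictors.index(predictor)])


def _fit_gaussian(X: np.ndarray, y: np.ndarray, lam: float):
    n, p = X.shape
    xm = X.mean(axis=0)
    Xc = X - xm
    ym = y.mean()
    G = Xc.T @ Xc / n
    c = Xc.T @ (y - ym) / n
    beta = np.zeros(p)
    cd_gram(G, c, beta, lam, CD_TOL, CD_SWEEPS)
    b0 = ym - xm @ beta
    return b0, beta


def _fit_binomial(X: np.ndarray, y: np.ndarray, lam: float):
    pbar = y.mean()
    if pbar <= 0 or pbar >= 1:
        raise ValueError("degenerate (constant) binary response")
    b0 = float(np.log(pbar / (1 - pbar)))
    beta = np.zeros(X.shape[1])
    b0, beta = logistic_lasso(
        np.ascontiguousarray(X, dtype=np.float64),
        np.ascontiguousarray(y, dtype=np.float64),
        b0, beta, lam, LOGISTIC_TOL, LOGISTIC_MAX_OUTER, CD_TOL, CD_SWEEPS,
    )
    return b0, beta


def penalized_gradient(X, y, family, intercept, beta):
    """Gradient of the smooth part of the objective w.r.t. beta."""
    n = X.shape[0]
    eta = intercept + X @ beta
    if family == "gaussian":
        return -(X.T @ (y - eta)) / n
    mu = 1.0 / (1.0 + np.exp(-eta))
    return (X.T @ (mu - y)) / n


def kkt_violation(X, y, family, intercept, beta, lam) -> float:
    """Worst violation of the l1 subgradient optimality conditions.

    Zero coefficients require |grad_j| <= lam; active coefficients
    require grad_j = -sign(beta_j) * lam.
    """
    g = penalized_gradient(X, y, family, intercept, beta)
    active = beta != 0
    viol = 0.0
    if (~active).any():
        viol = max(viol, float(np.max(np.abs(g[~active])) - lam)) if (~active).sum() else viol
        viol = max(viol, 0.0)
    if active.any():
        viol = max(viol, float(np.max(np.abs(g[active] + np.sign(beta[active]) * lam))))
    # intercept is unpenalized: its gradient must vanish
    if family == "gaussian":
        gi = -(y - intercept - X @ beta).mean()
    else:
        gi = (1.0 / (1.0 + np.exp(-(intercept + X @ beta))) - y).mean()
    return max(viol, abs(float(gi)))


def objective(X, y, family, intercept, beta, lam) -> float:
    """The penalized objective value (for oracle comparisons)."""
    n = X.shape[0]
    eta = intercept + X @ beta
    if family == "gaussian":
        val = 0.5 * np.sum((y - eta) ** 2) / n
    else:
        s = (1.0 - 2.0 * y) * eta
        val = np.mean(np.logaddexp(0.0, s))
    return float(val + lam * np.abs(beta).sum())


def fit_nodewise(
    predictors: np.ndarray,
    response: np.ndarray,
    family: str = "gaussian",
    lam: float = 0.0,
    node: str = "y",
    predictor_names: list[str] | None = None,
    check_kkt: bool = True,
) -> NodewiseFit:
    """Solve one penalized nodewise regression at a fixed penalty.

    Predictors are assumed standardized (continuous) or 0/1 (binary).
    """
    X = np.asarray(predictors, float)
    y = np.asarray(response, float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in inputs")
    if family == "gaussian":
        b0, beta = _fit_gaussian(X, y, lam)
    elif family == "binomial":
        b0, beta = _fit_binomial(X, y, lam)
    else:
        raise ValueError(f"unknown family {family!r}")
    fit = NodewiseFit(
        node=node,
        family=family,
        predictors=list(predictor_names or [f"x{j}" for j in range(X.shape[1])]),
        intercept=float(b0),
        coefficients=beta,
        lam=float(lam),
    )
    if check_kkt:
        fit.kkt_violation = kkt_violation(X, y, family, b0, beta, lam)
    return fit
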