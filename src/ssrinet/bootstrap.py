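"""Nonparametric bootstrap of the network estimation.

Rows of a week's complete-case matrix are resampled with replacement at
the original n and the entire estimation procedure — standardization,
per-node cross-validated penalty selection with replicate-derived fold
seeds, full refit and edge aggregation — is re-run on each replicate
(100 by default).  Summaries report the empirical 5%/95% quantiles
(type-7 order statistics) of each edge's replicate distribution and
whether the interval includes zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MGMConfig, MixedGraphicalModel, NetworkResults, NodeSpec
from .seeds import derive_seed

logger = logging.getLogger(__name__)


def quantile(values, q) -> float:
    """Linear-interpolation (type-7) empirical quantile."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("empty input")
    if np.ndim(q) == 0 and not 0 <= q <= 1:
        raise ValueError("q must lie in [0, 1]")
    return float(np.quantile(v, q, method="linear"))


@dataclass
class BootstrapSummary:
    """Sampling distribution of one edge weight under row resampling."""

    edge: tuple[str, str]
    B: int
    estimates: np.ndarray
    point_estimate: float
    q05: float = field(init=False)
    q95: float = field(init=False)
    prop_nonzero: float = field(init=False)
    includes_zero: bool = field(init=False)

    def __post_init__(self):
        est = np.asarray(self.estimates, float)
        if len(est) != self.B:
            raise ValueError("estimates length must equal B")
        self.q05 = quantile(est, 0.05)
        self.q95 = quantile(est, 0.95)
        self.prop_nonzero = float(np.mean(est != 0))
        self.includes_zero = bool(self.q05 <= 0 <= self.q95)


def bootstrap_network(
    week_df: pd.DataFrame,
    nodes: list[NodeSpec],
    config: MGMConfig | None = None,
    B: int = 100,
    seed: int = 0,
    edges_of_interest: list[tuple[str, str]] | None = None,
    reselect_lambda: bool = True,
    point: NetworkResults | None = None,
) -> dict[tuple[str, str], BootstrapSummary]:
    """Bootstrap the full network estimation on one week matrix.

    By default summaries cover all treatment-symptom edges; pass
    ``edges_of_interest`` to restrict.  ``reselect_lambda=False``
    freezes each node's penalty at the full-sample CV choice inside the
    replicates (a faster, less conservative variant).  Replicate-level
    estimation failures are recorded and skipped; more than 20% failures
    is an error.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    config = config or MGMConfig()
    if point is None:
        point = MixedGraphicalModel(week_df, nodes, config).fit(seed=derive_seed(seed, "point"))
    treat = point.treatment
    edges = edges_of_interest or [(treat, s) for s in point.symptoms]
    for a, b in edges:
        if a not in point.node_names or b not in point.node_names:
            raise ValueError(f"unknown edge ({a}, {b})")

    frozen = None if reselect_lambda else point.lambdas()
    n = len(week_df)
    estimates: dict[tuple[str, str], list[float]] = {e: [] for e in edges}
    failures = 0
    for b_rep in range(B):
        rng = np.random.default_rng(derive_seed(seed, "resample", b_rep))
        idx = rng.integers(0, n, size=n)
        sample = week_df.iloc[idx].reset_index(drop=True)
        try:
            model = MixedGraphicalModel(sample, nodes, config)
            if frozen is None:
                rep = model.fit(seed=derive_seed(seed, "replicate", b_rep))
            else:
                rep = _fit_frozen(model, frozen)
        except Exception as exc:  # noqa: BLE001 - replicate failures are data events
            failures += 1
            logger.warning("bootstrap replicate %d failed: %s", b_rep, exc)
            continue
        for e in edges:
            estimates[e].append(rep.weight(*e))
    if failures > 0.2 * B:
        raise RuntimeError(f"{failures}/{B} bootstrap replicates failed")
    eff_B = B - failures
    return {
        e: BootstrapSummary(edge=e, B=eff_B, estimates=np.asarray(v),
                            point_estimate=point.weight(*e))
        for e, v in estimates.items()
    }


def _fit_frozen(model: MixedGraphicalModel, lambdas: dict[str, float]) -> NetworkResults:
    """Refit every nodewise regression at fixed (full-sample) penalties."""
    from .model import combine_nodewise
    from .solver import fit_nodewise

    names = [nd.name for nd in model.nodes]
    net_names = [nd.name for nd in model.nodes if nd.role != "covariate"]
    fits = {}
    for j, nd in enumerate(model.nodes):
        if nd.role == "covariate":
            continue
        response = model.X[:, j] if nd.kind == "binary" else model.Xs[:, j]
        pred_idx = [k for k in range(len(names)) if k != j]
        Xp = model.Xs[:, pred_idx]
        family = "binomial" if nd.kind == "binary" else "gaussian"
        fit = fit_nodewise(Xp, response, family, lambdas[nd.name], node=nd.name,
                           predictor_names=[names[k] for k in pred_idx],
                           check_kkt=False)
        for t, k in enumerate(pred_idx):
            s = model.pred_scales[k]
            if s != 1.0:
                fit.intercept -= fit.coefficients[t] * model.X[:, k].mean() / s
                fit.coefficients[t] /= s
        fits[nd.name] = fit
    weights, signs = combine_nodewise(fits, net_names, model.config.rule)
    return NetworkResults(
        nodes=[nd for nd in model.nodes if nd.role != "covariate"],
        covariates=[nd for nd in model.nodes if nd.role == "covariate"],
        weights=weights, signs=signs, rule=model.config.rule, fits=fits,
        n_samples=len(model.data), seed=-1, model=model,
    )


def summaries_frame(summaries: dict[tuple[str, str], BootstrapSummary]) -> pd.DataFrame:
    """Tidy CSV-ready table of bootstrap summaries."""
    rows = [{
        "node_a": e[0], "node_b": e[1], "B": s.B,
        "q05": s.q05, "q95": s.q95,
        "prop_nonzero": s.prop_nonzero,
        "includes_zero": s.includes_zero,
        "point_estimate": s.point_estimate,
    } for e, s in summaries.items()]
    return pd.DataFrame(rows)
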