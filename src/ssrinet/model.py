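"""Mixed graphical model over a binary treatment node and continuous
symptom nodes, statsmodels-style.

:class:`MixedGraphicalModel` holds one assessment's complete-case
matrix and the node roles; :meth:`MixedGraphicalModel.fit` runs the
nodewise estimation (per-node lambda grid, 10-fold CV selection,
full-data refit with a KKT certificate) and returns a
:class:`NetworkResults` carrying the symmetric edge-weight matrix,
signs, the per-node fits for audit, and export/plot/bootstrap helpers.

Edges aggregate the two nodewise coefficients of a node pair: under the
AND rule (default) an edge is present only if both coefficients are
nonzero, with weight (|a|+|b|)/2 and their shared sign; under OR, if at
least one is nonzero.  Disagreeing signs keep the magnitude with an
undefined sign and a logged warning.  Covariate nodes (e.g. trial-id
dummies, age) enter every nodewise regression as penalized predictors
but are reported with no edges of their own.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cv import select_lambda_cv
from .seeds import derive_seed
from .solver import NodewiseFit, fit_nodewise, lambda_grid, standardize

logger = logging.getLogger(__name__)

SIGN_UNDEFINED = 2  # sentinel in the sign matrix for disagreeing signs


@dataclass(frozen=True)
class NodeSpec:
    """One network node: its name, data kind, and role."""

    name: str
    kind: str = "continuous"  # {continuous, binary}
    role: str = "symptom"  # {treatment, symptom, covariate}

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.role not in ("treatment", "symptom", "covariate"):
            raise ValueError(f"unknown node role {self.role!r}")


def default_nodes(item_names: list[str], covariates: list[str] | None = None,
                  covariate_kinds: dict[str, str] | None = None) -> list[NodeSpec]:
    """Treatment + symptom nodes (+ predictor-only covariates)."""
    nodes = [NodeSpec("arm", "binary", "treatment")]
    nodes += [NodeSpec(n, "continuous", "symptom") for n in item_names]
    kinds = covariate_kinds or {}
    for c in covariates or []:
        nodes.append(NodeSpec(c, kinds.get(c, "continuous"), "covariate"))
    return nodes


@dataclass
class MGMConfig:
    """Estimation options for one network fit."""

    rule: str = "AND"
    folds: int = 10
    n_lambda: int = 50
    min_ratio: float = 1e-4
    lambda_policy: str = "min"  # or "1se"

    def __post_init__(self):
        if self.rule not in ("AND", "OR"):
            raise ValueError("rule must be AND or OR")


def combine_nodewise(fits: dict[str, NodewiseFit], node_names: list[str],
                     rule: str = "AND"):
    """Aggregate nodewise coefficients into symmetric weights and signs.

    For pair (j, k) let ``a`` be k's coefficient in j's fit and ``b``
    j's coefficient in k's fit.  AND keeps the edge iff both are
    nonzero, OR iff at least one is; the magnitude is (|a|+|b|)/2 over
    present edges.  The sign is the shared sign (or the nonzero one's
    under OR); disagreeing signs are marked undefined with a warning.
    """
    if rule not in ("AND", "OR"):
        raise ValueError("rule must be AND or OR")
    m = len(node_names)
    for name in node_names:
        if name not in fits:
            raise ValueError(f"missing nodewise fit for node {name!r}")
    weights = np.zeros((m, m))
    signs = np.zeros((m, m), dtype=np.int64)
    for j in range(m):
        for k in range(j + 1, m):
            a = fits[node_names[j]].coef(node_names[k])
            b = fits[node_names[k]].coef(node_names[j])
            present = (a != 0 and b != 0) if rule == "AND" else (a != 0 or b != 0)
            if not present:
                continue
            w = (abs(a) + abs(b)) / 2.0
            sa, sb = np.sign(a), np.sign(b)
            if a == 0 or b == 0:
                s = int(sa + sb)  # the nonzero one's sign (OR rule)
            elif sa == sb:
                s = int(sa)
            else:
                s = SIGN_UNDEFINED
                warnings.warn(
                    f"disagreeing nodewise signs for edge {node_names[j]}--{node_names[k]}; "
                    "magnitude kept, sign undefined",
                    stacklevel=2,
                )
            weights[j, k] = weights[k, j] = w * (s if s in (-1, 1) else 1)
            signs[j, k] = signs[k, j] = s
    return weights, signs


class MixedGraphicalModel:
    """Model object: one assessment's complete-case data plus node roles.

    Parameters
    ----------
    data : DataFrame
        Complete-case matrix whose columns include every node name.
    nodes : list of NodeSpec
        Exactly one treatment node; symptom nodes become network nodes;
        covariate nodes are predictors only.
    config : MGMConfig, optional
    """

    def __init__(self, data: pd.DataFrame, nodes: list[NodeSpec],
                 config: MGMConfig | None = None):
        self.config = config or MGMConfig()
        self.nodes = list(nodes)
        n_treat = sum(nd.role == "treatment" for nd in self.nodes)
        if n_treat != 1:
            raise ValueError(f"exactly one treatment node required, got {n_treat}")
        names = [nd.name for nd in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicated node names")
        missing = [n for n in names if n not in data.columns]
        if missing:
            raise ValueError(f"data lacks node columns: {missing}")
        sub = data[names]
        if sub.isna().any().any():
            raise ValueError(
                "missing values in node columns; apply complete-case filtering first"
            )
        if len(sub) <= len(names):
            raise ValueError("need more rows than nodes")
        self.data = sub.reset_index(drop=True)
        self.X, self.centers, self.scales = standardize(
            sub.to_numpy(dtype=float), [nd.kind for nd in self.nodes], names
        )
        # For penalization, binary predictor columns are additionally put on
        # unit-SD scale (as glmnet-family estimators do internally) so that
        # the l1 penalty bites evenly across predictors; the fitted
        # coefficients are back-transformed to per-unit (0/1) scale so that
        # treatment edges stay in per-SD-of-symptom units.
        self.Xs = self.X.copy()
        self.pred_scales = np.ones(len(self.nodes))
        for j, nd in enumerate(self.nodes):
            if nd.kind == "binary":
                s = self.X[:, j].std(ddof=1)
                if s == 0:
                    raise ValueError(f"constant binary column {nd.name!r} (single-arm data?)")
                self.Xs[:, j] = (self.X[:, j] - self.X[:, j].mean()) / s
                self.pred_scales[j] = s

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, symptoms: list[str],
                       treatment: str = "arm", covariates: list[str] | None = None,
                       covariate_kinds: dict[str, str] | None = None,
                       config: MGMConfig | None = None) -> "MixedGraphicalModel":
        nodes = [NodeSpec(treatment, "binary", "treatment")]
        nodes += [NodeSpec(s, "continuous", "symptom") for s in symptoms]
        kinds = covariate_kinds or {}
        for c in covariates or []:
            kind = kinds.get(c)
            if kind is None:
                vals = data[c].dropna().unique()
                kind = "binary" if set(vals) <= {0, 1} else "continuous"
            nodes.append(NodeSpec(c, kind, "covariate"))
        return cls(data, nodes, config)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0) -> "NetworkResults":
        """Estimate the network: per-node CV lambda selection and refit."""
        cfg = self.config
        names = [nd.name for nd in self.nodes]
        net_names = [nd.name for nd in self.nodes if nd.role != "covariate"]
        fits: dict[str, NodewiseFit] = {}
        for j, nd in enumerate(self.nodes):
            if nd.role == "covariate":
                continue
            # binary responses stay 0/1; continuous responses are standardized
            response = self.X[:, j] if nd.kind == "binary" else self.Xs[:, j]
            pred_idx = [k for k in range(len(names)) if k != j]
            pred_names = [names[k] for k in pred_idx]
            Xp = self.Xs[:, pred_idx]
            family = "binomial" if nd.kind == "binary" else "gaussian"
            grid = lambda_grid(Xp, response, family, cfg.n_lambda, cfg.min_ratio)
            node_seed = derive_seed(seed, "cv", nd.name)
            lam, curve = select_lambda_cv(
                Xp, response, family, grid, folds=cfg.folds, seed=node_seed,
                policy=cfg.lambda_policy,
            )
            fit = fit_nodewise(Xp, response, family, lam, node=nd.name,
                               predictor_names=pred_names)
            fit.cv_curve = curve
            # back-transform binary-predictor coefficients to per-unit scale
            for t, k in enumerate(pred_idx):
                s = self.pred_scales[k]
                if s != 1.0:
                    fit.intercept -= fit.coefficients[t] * self.X[:, k].mean() / s
                    fit.coefficients[t] /= s
            if not np.isnan(fit.kkt_violation) and fit.kkt_violation > 1e-6:
                logger.warning("KKT violation %.2e for node %s", fit.kkt_violation, nd.name)
            fits[nd.name] = fit
        weights, signs = combine_nodewise(fits, net_names, cfg.rule)
        return NetworkResults(
            nodes=[nd for nd in self.nodes if nd.role != "covariate"],
            covariates=[nd for nd in self.nodes if nd.role == "covariate"],
            weights=weights,
            signs=signs,
            rule=cfg.rule,
            fits=fits,
            n_samples=len(self.data),
            seed=seed,
            model=self,
        )


@dataclass
class NetworkResults:
    """Fitted symptom network: symmetric weights over treatment+symptoms."""

    nodes: list[NodeSpec]
    covariates: list[NodeSpec]
    weights: np.ndarray
    signs: np.ndarray
    rule: str
    fits: dict[str, NodewiseFit]
    n_samples: int
    seed: int
    model: MixedGraphicalModel | None = None

    @property
    def node_names(self) -> list[str]:
        return [nd.name for nd in self.nodes]

    @property
    def treatment(self) -> str:
        return next(nd.name for nd in self.nodes if nd.role == "treatment")

    @property
    def symptoms(self) -> list[str]:
        return [nd.name for nd in self.nodes if nd.role == "symptom"]

    def weight(self, a: str, b: str) -> float:
        i, j = self.node_names.index(a), self.node_names.index(b)
        return float(self.weights[i, j])

    def treatment_row(self) -> pd.Series:
        """Signed treatment-symptom edge weights (the direct effects)."""
        i = self.node_names.index(self.treatment)
        return pd.Series(
            {s: float(self.weights[i, self.node_names.index(s)]) for s in self.symptoms},
            name="direct_effect",
        )

    def lambdas(self) -> dict[str, float]:
        return {k: f.lam for k, f in self.fits.items()}

    def edge_list(self) -> pd.DataFrame:
        rows = []
        names = self.node_names
        sign_repr = {1: "+", -1: "-", 0: "0", SIGN_UNDEFINED: "undefined"}
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if self.weights[i, j] != 0:
                    rows.append({
                        "node_a": names[i], "node_b": names[j],
                        "weight": float(self.weights[i, j]),
                        "sign": sign_repr[int(self.signs[i, j])],
                        "rule": self.rule,
                    })
        df = pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "sign", "rule"])
        return df.sort_values("weight", key=abs, ascending=False, kind="mergesort").reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "Mixed graphical model (nodewise lasso, "
            f"{self.rule} rule), n = {self.n_samples}",
            f"nodes: 1 treatment ({self.treatment}) + {len(self.symptoms)} symptoms"
            + (f" + {len(self.covariates)} covariate predictors" if self.covariates else ""),
            "",
            f"{'edge':<40s}{'weight':>9s}  sign",
        ]
        for _, row in self.edge_list().iterrows():
            lines.append(
                f"{row.node_a + ' -- ' + row.node_b:<40s}{row.weight:>9.4f}  {row.sign}"
            )
        return "\n".join(lines)

    # deferred imports keep matplotlib/networkx out of the numeric path
    def to_graphml(self, path) -> None:
        from . import io
        io.write_graphml(self, path)

    def to_json_bundle(self, path) -> None:
        from . import io
        io.write_network_json(self, path)

    def bootstrap(self, B: int = 100, seed: int = 0, edges_of_interest=None,
                  reselect_lambda: bool = True):
        from .bootstrap import bootstrap_network
        if self.model is None:
            raise ValueError("results were built without a model; bootstrap unavailable")
        return bootstrap_network(self.model.data, self.model.nodes, self.model.config,
                                 B=B, seed=seed, edges_of_interest=edges_of_interest,
                                 reselect_lambda=reselect_lambda, point=self)

    def plot(self, ax=None):
        from .plotting import plot_network
        return plot_network(self, ax=ax)


def estimate_network(data: pd.DataFrame, nodes: list[NodeSpec],
                     config: MGMConfig | None = None, seed: int = 0) -> NetworkResults:
    """Functional wrapper: build the model and fit in one call."""
    return MixedGraphicalModel(data, nodes, config).fit(seed=seed)
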