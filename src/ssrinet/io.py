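"""File formats: long-format trial CSV, edge lists, GraphML, JSON bundles.

The trial CSV schema is ``patient_id, trial_id, arm, age, sex, week``
followed by the 17 item columns; absent scores are empty fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .items import ItemSpec, hdrs_battery
from .model import SIGN_UNDEFINED, NetworkResults
from .simulate import META_COLUMNS, TrialDataset


def write_trial_csv(data: TrialDataset, path: str | Path) -> None:
    cols = META_COLUMNS + data.item_names
    frame = data.frame[cols].copy()
    frame.to_csv(path, index=False)


def read_trial_csv(path: str | Path, items: list[ItemSpec] | None = None,
                   latent: bool = False) -> TrialDataset:
    """Read and validate a long-format trial CSV.

    Out-of-range, non-integer (for ordinal data) and duplicated
    (patient, week) records are rejected with row-numbered messages;
    empty cells parse as absent scores.
    """
    items = items or hdrs_battery()
    frame = pd.read_csv(path)
    expected = META_COLUMNS + [it.name for it in items]
    if list(frame.columns) != expected:
        raise ValueError(
            f"schema mismatch: expected columns {expected}, found {list(frame.columns)}"
        )
    dup = frame.duplicated(subset=["patient_id", "week"])
    if dup.any():
        i = int(dup.idxmax())
        raise ValueError(
            f"row {i + 2}: duplicated (patient, week) pair "
            f"({frame.loc[i, 'patient_id']}, {frame.loc[i, 'week']})"
        )
    if not latent:
        for it in items:
            col = pd.to_numeric(frame[it.name], errors="coerce")
            present = frame[it.name].notna()
            bad = present & ((col < 0) | (col > it.scale_max))
            if bad.any():
                i = int(bad.idxmax())
                raise ValueError(
                    f"row {i + 2}: score {frame.loc[i, it.name]} outside "
                    f"[0, {it.scale_max}] for item {it.name!r}"
                )
            nonint = present & col.notna() & (col != np.round(col))
            if nonint.any():
                i = int(nonint.idxmax())
                raise ValueError(
                    f"row {i + 2}: non-integer score {frame.loc[i, it.name]} "
                    f"for item {it.name!r}"
                )
    ds = TrialDataset(frame=frame, items=items, latent=latent)
    ds.validate()
    return ds


def write_edgelist_csv(results: NetworkResults, path: str | Path) -> None:
    results.edge_list().to_csv(path, index=False)


def write_graphml(results: NetworkResults, path: str | Path) -> None:
    g = nx.Graph()
    for nd in results.nodes:
        g.add_node(nd.name, kind=nd.kind, role=nd.role)
    for _, row in results.edge_list().iterrows():
        g.add_edge(row.node_a, row.node_b, weight=float(row.weight), sign=str(row.sign))
    nx.write_graphml(g, path)


def write_network_json(results: NetworkResults, path: str | Path) -> None:
    """Full JSON bundle: weights, signs, per-node lambdas and CV curves."""
    sign_repr = {1: "+", -1: "-", 0: "0", SIGN_UNDEFINED: "undefined"}
    payload = {
        "nodes": [{"name": nd.name, "kind": nd.kind, "role": nd.role}
                  for nd in results.nodes],
        "rule": results.rule,
        "n_samples": results.n_samples,
        "seed": results.seed,
        "weights": results.weights.tolist(),
        "signs": [[sign_repr[int(s)] for s in row] for row in results.signs],
        "nodewise": {
            name: {
                "family": f.family,
                "lambda": f.lam,
                "intercept": f.intercept,
                "coefficients": dict(zip(f.predictors, map(float, f.coefficients))),
                "kkt_violation": None if np.isnan(f.kkt_violation) else f.kkt_violation,
                "cv_curve": {f"{l:.10g}": v for l, v in f.cv_curve.items()},
            }
            for name, f in results.fits.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))
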