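"""Per-week network analysis pipeline.

Implements the per-assessment workflow: complete-case filtering at each
week, independent network estimation per week (no parameter sharing),
extraction of the treatment node's edge trajectory (the direct
symptom-specific treatment effects), descriptive indirect-effect scores
as treatment -> mediator -> target 2-path edge products, cross-week
stability correlations of the direct-effect vectors, and
covariate-adjusted sensitivity networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MGMConfig, MixedGraphicalModel, NetworkResults, default_nodes
from .seeds import derive_seed
from .simulate import TrialDataset


def complete_case_week(data: TrialDataset, week: int, covariates: list[str] | None = None):
    """Complete-case matrix for one assessment week.

    Retains exactly the patients with all items present at that week;
    returns ``(week_frame, retained_patient_ids)`` where the frame holds
    the treatment column, the 17 item columns and any requested
    covariates.
    """
    frame = data.frame
    if week not in set(frame["week"]):
        raise ValueError(f"week {week} not present in the data")
    sub = frame[frame["week"] == week]
    keep = sub[data.item_names].notna().all(axis=1)
    if covariates:
        dup = [c for c in covariates if c in data.item_names]
        if dup:
            raise ValueError(f"covariate duplicates a symptom column: {dup}")
        missing = [c for c in covariates if c not in sub.columns]
        if missing:
            raise ValueError(f"covariates not in data: {missing}")
        keep &= sub[covariates].notna().all(axis=1)
    sub = sub[keep]
    cols = ["arm"] + data.item_names + list(covariates or [])
    return sub[cols].reset_index(drop=True), sub["patient_id"].tolist()


def _prepare_covariates(week_df: pd.DataFrame, covariates: list[str] | None):
    """One-hot encode categorical covariates (trial-id); pass numeric ones."""
    if not covariates:
        return week_df, [], {}
    out = week_df.copy()
    cov_cols: list[str] = []
    kinds: dict[str, str] = {}
    for c in covariates:
        col = out[c]
        if c == "trial_id" or col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col.astype("category"), prefix=c, dtype=float)
            # full one-hot; the penalty handles the redundancy
            for dc in dummies.columns:
                out[dc] = dummies[dc]
                cov_cols.append(dc)
                kinds[dc] = "binary"
            out = out.drop(columns=[c])
        else:
            vals = set(col.dropna().unique())
            kinds[c] = "binary" if vals <= {0, 1} else "continuous"
            cov_cols.append(c)
    return out, cov_cols, kinds


def fit_weekly_networks(
    data: TrialDataset,
    weeks,
    config: MGMConfig | None = None,
    seed: int = 0,
    covariates: list[str] | None = None,
) -> dict[int, NetworkResults]:
    """One independently estimated network per follow-up week.

    Per-week seeds derive deterministically from the master seed, so the
    map is reproducible and weeks can be recomputed in isolation.
    """
    config = config or MGMConfig()
    out: dict[int, NetworkResults] = {}
    for w in weeks:
        week_df, _ = complete_case_week(data, w, covariates)
        week_df, cov_cols, kinds = _prepare_covariates(week_df, covariates)
        nodes = default_nodes(data.item_names, cov_cols, kinds)
        model = MixedGraphicalModel(week_df, nodes, config)
        out[int(w)] = model.fit(seed=derive_seed(seed, "week", w))
    return out


@dataclass
class DirectEffectTrajectory:
    """Weeks x symptoms matrix of signed treatment-edge weights.

    Negative values mean lower symptom scores under active treatment
    (beneficial); missing weeks are simply not rows, never imputed.
    """

    values: pd.DataFrame  # index = week, columns = symptoms

    @property
    def weeks(self) -> list[int]:
        return list(self.values.index)

    @property
    def symptoms(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path) -> None:
        tidy = self.values.reset_index(names="week").melt(
            id_vars="week", var_name="symptom", value_name="direct_effect"
        )
        tidy.to_csv(path, index=False)


def direct_effects(models: dict[int, NetworkResults]) -> DirectEffectTrajectory:
    """Extract the signed treatment-edge row of each weekly network."""
    weeks = sorted(models)
    symptom_sets = {tuple(models[w].symptoms) for w in weeks}
    if len(symptom_sets) != 1:
        raise ValueError("weekly networks have inconsistent symptom sets")
    rows = {w: models[w].treatment_row() for w in weeks}
    values = pd.DataFrame(rows).T
    values.index.name = "week"
    return DirectEffectTrajectory(values=values)


def indirect_effects(model: NetworkResults, max_path_len: int = 2) -> pd.DataFrame:
    """Descriptive 2-path indirect-effect table for one network.

    Enumerates treatment -> mediator -> target paths whose two edges are
    both nonzero and scores each by the product of the edge weights.
    This is a transparent surrogate for reading indirect effects off the
    graph; it is not a formal mediation test.
    """
    if max_path_len != 2:
        raise NotImplementedError("only 2-paths are defined")
    treat = model.treatment
    rows = []
    for mediator in model.symptoms:
        w_tm = model.weight(treat, mediator)
        if w_tm == 0:
            continue
        for target in model.symptoms:
            if target == mediator:
                continue
            w_mt = model.weight(mediator, target)
            if w_mt == 0:
                continue
            rows.append({
                "mediator": mediator,
                "target": target,
                "treatment_edge": w_tm,
                "mediator_target_edge": w_mt,
                "product": w_tm * w_mt,
            })
    df = pd.DataFrame(rows, columns=["mediator", "target", "treatment_edge",
                                     "mediator_target_edge", "product"])
    return df.sort_values("product", key=abs, ascending=False, kind="mergesort").reset_index(drop=True)


def stability_correlation(traj: DirectEffectTrajectory) -> dict[tuple[int, int], float]:
    """Pearson r between direct-effect vectors of consecutive weeks.

    A zero-variance vector makes the pair's correlation undefined (NaN),
    not an error.
    """
    weeks = traj.weeks
    if len(weeks) < 2:
        raise ValueError("need at least two weeks")
    if len(traj.symptoms) < 3:
        raise ValueError("need at least three symptoms")
    out: dict[tuple[int, int], float] = {}
    for w1, w2 in zip(weeks[:-1], weeks[1:]):
        a = traj.values.loc[w1].to_numpy(float)
        b = traj.values.loc[w2].to_numpy(float)
        if a.std() == 0 or b.std() == 0:
            out[(w1, w2)] = float("nan")
        else:
            out[(w1, w2)] = float(np.corrcoef(a, b)[0, 1])
    return out


def adjusted_networks(
    data: TrialDataset,
    weeks,
    covariates: list[str],
    config: MGMConfig | None = None,
    seed: int = 0,
) -> dict[int, dict]:
    """Covariate-adjusted sensitivity networks.

    Re-runs the weekly estimation with the covariates as penalized
    predictor blocks in every nodewise regression and reports, per week,
    the adjusted and unadjusted treatment rows side by side.
    """
    if not covariates:
        raise ValueError("no covariates given")
    unadj = fit_weekly_networks(data, weeks, config, seed=seed)
    adj = fit_weekly_networks(data, weeks, config, seed=seed, covariates=covariates)
    out: dict[int, dict] = {}
    for w in weeks:
        w = int(w)
        comparison = pd.DataFrame({
            "unadjusted": unadj[w].treatment_row(),
            "adjusted": adj[w].treatment_row(),
        })
        comparison["abs_change"] = (comparison["adjusted"] - comparison["unadjusted"]).abs()
        out[w] = {"unadjusted": unadj[w], "adjusted": adj[w], "comparison": comparison}
    return out
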