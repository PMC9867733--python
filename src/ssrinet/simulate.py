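"""Randomized-trial simulator.

Generates long-format patient x week records with the statistical
structure the network analysis assumes: a Bernoulli treatment
assignment, correlated latent symptom vectors drawn from a Gaussian
graphical model, a per-week marginal treatment mean-shift, per-trial
random intercepts, ordinal discretisation through item cut-points, and
independent per-week assessment missingness.

With ``latent_only=True`` the continuous latent values are emitted
directly so that the estimation model's assumptions hold exactly; this
separates solver correctness from discretisation bias in recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .items import ItemSpec
from .truth import WEEKS, GroundTruth

META_COLUMNS = ["patient_id", "trial_id", "arm", "age", "sex", "week"]


@dataclass
class TrialDataset:
    """Long-format trial records: one row per patient x assessment week.

    ``frame`` columns: patient_id, trial_id, arm (0 placebo / 1 SSRI),
    age, sex, week, then one column per item (NaN = absent score).
    """

    frame: pd.DataFrame
    items: list[ItemSpec]
    latent: bool = False

    @property
    def item_names(self) -> list[str]:
        return [it.name for it in self.items]

    @property
    def weeks(self) -> list[int]:
        return sorted(self.frame["week"].unique())

    def validate(self) -> None:
        missing = [c for c in META_COLUMNS + self.item_names if c not in self.frame.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        dup = self.frame.duplicated(subset=["patient_id", "week"])
        if dup.any():
            row = self.frame.loc[dup.idxmax()]
            raise ValueError(
                f"duplicated (patient, week) pair: ({row['patient_id']}, {row['week']})"
            )
        per_pat = self.frame.groupby("patient_id")[["arm", "age", "sex"]].nunique()
        if (per_pat > 1).any().any():
            raise ValueError("arm, age and sex must be constant within patient")
        if not self.latent:
            for it in self.items:
                col = self.frame[it.name].dropna()
                if ((col < 0) | (col > it.scale_max)).any():
                    raise ValueError(f"{it.name}: score outside [0, {it.scale_max}]")
                if not np.allclose(col, np.round(col)):
                    raise ValueError(f"{it.name}: non-integer score in ordinal data")


def simulate_trial(
    gt: GroundTruth,
    n_patients: int,
    weeks=WEEKS,
    seed: int = 0,
    latent_only: bool = False,
) -> TrialDataset:
    """Simulate one randomized trial dataset.

    Per patient: ``arm ~ Bernoulli(p_treat)``; a trial stratum uniform
    over ``n_trials`` contributing an intercept ``~ N(0, trial_shift_sd^2)``
    shared by all of the trial's patients and items; per retained week
    ``w`` a latent vector ``y = mu + arm * m_w + trial_shift + z`` with
    ``z ~ MVN(0, Omega^{-1})`` and ``m_w = gt.marginal_shift(w)`` (equal
    to ``delta[w]`` under marginal injection; under the default
    conditional injection it is the shift whose conditional per-symptom
    effect equals ``delta[w]``).  Ordinal scores count the cut-points
    below the latent value (hard clip at the extreme cut-points).  Each
    week's assessment is independently absent with ``missing_rate[w]``.
    Byte-identical output for identical inputs and seed.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    weeks = sorted(int(w) for w in weeks)
    if 0 not in weeks:
        raise ValueError("weeks must contain the baseline week 0")
    unknown = [w for w in weeks if w not in gt.delta]
    if unknown:
        raise ValueError(f"no treatment-shift defined for week(s) {unknown}")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5514]))
    p = len(gt.items)
    n = int(n_patients)

    arm = (rng.random(n) < gt.p_treat).astype(np.int64)
    trial_id = rng.integers(0, gt.n_trials, size=n)
    trial_effects = rng.normal(0.0, gt.trial_shift_sd, size=gt.n_trials)
    age = rng.normal(44.0, 14.5, size=n)
    # truncate by redrawing out-of-range values
    bad = (age < 18) | (age > 90)
    while bad.any():
        age[bad] = rng.normal(44.0, 14.5, size=bad.sum())
        bad = (age < 18) | (age > 90)
    sex = (rng.random(n) < 0.595).astype(np.int64)

    chol = np.linalg.cholesky(gt.Sigma)
    frames = []
    for w in weeks:
        z = rng.standard_normal((n, p)) @ chol.T
        y = gt.mu + np.outer(arm, gt.marginal_shift(w)) + trial_effects[trial_id][:, None] + z
        present = rng.random(n) >= gt.missing_rate.get(w, 0.0)
        if latent_only:
            scores = y
        else:
            scores = np.empty((n, p))
            for i, it in enumerate(gt.items):
                scores[:, i] = np.searchsorted(gt.cutpoints[i], y[:, i]).astype(float)
        scores = scores[present]
        df = pd.DataFrame(
            {
                "patient_id": np.arange(n)[present],
                "trial_id": trial_id[present],
                "arm": arm[present],
                "age": age[present],
                "sex": sex[present],
                "week": w,
            }
        )
        for i, it in enumerate(gt.items):
            df[it.name] = scores[:, i]
        frames.append(df)

    frame = pd.concat(frames, ignore_index=True)
    ds = TrialDataset(frame=frame, items=list(gt.items), latent=latent_only)
    ds.validate()
    return ds
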