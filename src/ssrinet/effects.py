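"""Classical (non-network) statistical track.

Baseline group comparisons with Bonferroni control, per-week overall
treatment effects via independent-samples Student t-tests and Cohen's d
(pooled-SD standardized mean difference, sign convention SSRI - placebo
so negative = beneficial), and the side-by-side comparison of overall
effects with the networks' direct effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import DirectEffectTrajectory, complete_case_week
from .simulate import TrialDataset

#: |Cohen's d| above which an overall effect counts as substantial when
#: flagging direct/overall discordance
DISCORDANCE_D = 0.15


def students_t(group_a, group_b, equal_var: bool = True):
    """Two-sided independent-samples t-test.

    Pooled-variance Student's t by default (df = n1 + n0 - 2), Welch via
    ``equal_var=False``.  Returns ``(t, df, p)``.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in groups")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = len(a) + len(b) - 2 if equal_var else float(res.df)
    return float(res.statistic), float(df), float(res.pvalue)


def cohens_d(group_a, group_b) -> float:
    """Pooled-SD standardized mean difference (group_a - group_b).

    Returns NaN when the pooled SD is zero (undefined effect size).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    t = np.asarray(table, float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in the 2x2 table")
    stat, p, _, expected = stats.chi2_contingency(t, correction=False)
    if (expected <= 0).any():
        raise ValueError("expected counts must be positive")
    return float(stat), float(p)


def bonferroni_alpha(n_tests: int, fwer: float = 0.05) -> float:
    """Per-test significance threshold controlling the family-wise rate."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < fwer < 1:
        raise ValueError("fwer must lie in (0, 1)")
    return fwer / n_tests


def baseline_table(data: TrialDataset, fwer: float = 0.05) -> pd.DataFrame:
    """Baseline (week 0) arm comparison of symptoms and covariates.

    Per symptom: per-arm mean (SD) and a Student t-test, flagged at the
    Bonferroni threshold fwer/17; age is tested at ``fwer`` and sex with
    an uncorrected chi-square, mirroring the convention of testing only
    the symptom family at the corrected level.
    """
    frame = data.frame
    base = frame[frame["week"] == 0]
    if base.empty:
        raise ValueError("no week-0 records")
    if base["arm"].nunique() < 2:
        raise ValueError("single-arm data: baseline comparison undefined")
    alpha_items = bonferroni_alpha(len(data.item_names), fwer)
    rows = []
    g1 = base[base["arm"] == 1]
    g0 = base[base["arm"] == 0]
    for name in data.item_names:
        a = g1[name].dropna().to_numpy()
        b = g0[name].dropna().to_numpy()
        t, df, p = students_t(a, b)
        rows.append({
            "variable": name, "kind": "symptom",
            "n_ssri": len(a), "n_placebo": len(b),
            "mean_ssri": a.mean(), "sd_ssri": a.std(ddof=1),
            "mean_placebo": b.mean(), "sd_placebo": b.std(ddof=1),
            "statistic": t, "df": df, "p": p,
            "alpha": alpha_items, "significant": p < alpha_items,
        })
    a = g1["age"].to_numpy()
    b = g0["age"].to_numpy()
    t, df, p = students_t(a, b)
    rows.append({
        "variable": "age", "kind": "covariate",
        "n_ssri": len(a), "n_placebo": len(b),
        "mean_ssri": a.mean(), "sd_ssri": a.std(ddof=1),
        "mean_placebo": b.mean(), "sd_placebo": b.std(ddof=1),
        "statistic": t, "df": df, "p": p, "alpha": fwer, "significant": p < fwer,
    })
    table = np.array([
        [(g1["sex"] == 1).sum(), (g1["sex"] == 0).sum()],
        [(g0["sex"] == 1).sum(), (g0["sex"] == 0).sum()],
    ])
    stat, p = chi_square_2x2(table)
    rows.append({
        "variable": "sex", "kind": "covariate",
        "n_ssri": len(g1), "n_placebo": len(g0),
        "mean_ssri": g1["sex"].mean(), "sd_ssri": float("nan"),
        "mean_placebo": g0["sex"].mean(), "sd_placebo": float("nan"),
        "statistic": stat, "df": 1.0, "p": p, "alpha": fwer, "significant": p < fwer,
    })
    return pd.DataFrame(rows)


def overall_effects(data: TrialDataset, weeks) -> pd.DataFrame:
    """Per week x symptom unconditional arm comparison (EffectSizeTable).

    Uses each week's complete cases — the same patients as the
    corresponding network estimation.
    """
    rows = []
    for w in weeks:
        week_df, _ = complete_case_week(data, w)
        g1 = week_df[week_df["arm"] == 1]
        g0 = week_df[week_df["arm"] == 0]
        for name in data.item_names:
            a = g1[name].to_numpy(float)
            b = g0[name].to_numpy(float)
            t, df, p = students_t(a, b)
            rows.append({
                "week": int(w), "symptom": name,
                "n_ssri": len(a), "n_placebo": len(b),
                "mean_ssri": a.mean(), "sd_ssri": a.std(ddof=1),
                "mean_placebo": b.mean(), "sd_placebo": b.std(ddof=1),
                "t": t, "df": df, "p": p,
                "cohens_d": cohens_d(a, b),
            })
    return pd.DataFrame(rows)


def direct_vs_overall(traj: DirectEffectTrajectory, table: pd.DataFrame) -> pd.DataFrame:
    """Side-by-side direct edge weight vs overall Cohen's d per week/symptom.

    Flags ``indirect_dominant`` when the overall effect is substantial
    (|d| >= 0.15) with no direct edge, and ``direct_dominant`` for the
    converse (a substantial direct edge, |weight| >= 0.15, with no
    comparable overall effect).
    """
    need = {"week", "symptom", "cohens_d"}
    if not need <= set(table.columns):
        raise ValueError(f"effect table lacks columns {sorted(need - set(table.columns))}")
    tidy = traj.values.reset_index(names="week").melt(
        id_vars="week", var_name="symptom", value_name="direct_effect"
    )
    merged = tidy.merge(table[["week", "symptom", "cohens_d"]], on=["week", "symptom"],
                        how="inner", validate="one_to_one")
    if len(merged) != len(tidy):
        raise ValueError("weeks/symptoms of trajectory and effect table do not match")
    d = merged["cohens_d"].abs()
    w = merged["direct_effect"].abs()
    merged["flag"] = ""
    merged.loc[(d >= DISCORDANCE_D) & (w == 0), "flag"] = "indirect_dominant"
    merged.loc[(w >= DISCORDANCE_D) & (d < DISCORDANCE_D), "flag"] = "direct_dominant"
    return merged
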