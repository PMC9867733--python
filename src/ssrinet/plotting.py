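"""Figures: direct-effect trajectories and per-week network diagrams.

Networks use a fixed circular layout with symptoms grouped by category
(no force-directed layout); trajectory lines are colored by category.
"""

from __future__ import annotations

import numpy as np

from .items import CATEGORIES, ItemSpec, hdrs_battery

_CATEGORY_COLORS = {
    "affective": "#c0392b",
    "cognitive": "#2980b9",
    "arousal_somatic": "#27ae60",
    "sleep": "#8e44ad",
    "insight": "#7f8c8d",
}


def _category_of(items: list[ItemSpec]) -> dict[str, str]:
    return {it.name: it.category for it in items}


def plot_trajectory(traj, items: list[ItemSpec] | None = None, ax=None):
    """Line chart of direct effects: weeks on x, edge weight on y,
    one category-colored line per symptom."""
    import matplotlib.pyplot as plt

    items = items or hdrs_battery()
    cats = _category_of(items)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    for symptom in traj.symptoms:
        color = _CATEGORY_COLORS.get(cats.get(symptom, ""), "#333333")
        ax.plot(traj.weeks, traj.values[symptom], marker="o", ms=3,
                color=color, lw=1.2, label=symptom)
    ax.axhline(0.0, color="black", lw=0.6)
    ax.set_xlabel("week of treatment")
    ax.set_ylabel("treatment-symptom edge weight")
    ax.set_title("Direct symptom-specific treatment effects")
    ax.legend(fontsize=6, ncol=2, frameon=False)
    return ax


def plot_network(results, items: list[ItemSpec] | None = None, ax=None,
                 threshold: float = 0.0):
    """Category-grouped circular network diagram for one week."""
    import matplotlib.pyplot as plt

    items = items or hdrs_battery()
    cats = _category_of(items)
    if ax is None:
        _, ax = plt.subplots(figsize=(6.5, 6.5))
    names = results.node_names
    treat = results.treatment
    symptoms = [n for n in names if n != treat]
    symptoms.sort(key=lambda s: (CATEGORIES.index(cats.get(s, "insight")), s))
    # treatment at the center, symptoms on a circle grouped by category
    pos = {treat: np.array([0.0, 0.0])}
    for i, s in enumerate(symptoms):
        a = 2 * np.pi * i / len(symptoms)
        pos[s] = np.array([np.cos(a), np.sin(a)])
    for _, row in results.edge_list().iterrows():
        if abs(row.weight) < threshold:
            continue
        p1, p2 = pos[row.node_a], pos[row.node_b]
        color = "#c0392b" if row.weight < 0 else "#2980b9"
        ax.plot([p1[0], p2[0]], [p1[1], p2[1]], color=color,
                lw=min(6.0, 25 * abs(row.weight)), alpha=0.75, zorder=1)
    for name, p in pos.items():
        if name == treat:
            ax.scatter(*p, s=500, marker="s", color="#f1c40f", zorder=2,
                       edgecolor="black")
        else:
            ax.scatter(*p, s=350, color=_CATEGORY_COLORS.get(cats.get(name, ""), "#999"),
                       zorder=2, edgecolor="black", linewidth=0.5)
        ax.annotate(name, p, ha="center", va="center", fontsize=4.5, zorder=3)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"Symptom network (n = {results.n_samples}, rule = {results.rule})")
    return ax


def plot_bootstrap_intervals(summaries_df, ax=None):
    """Interval plot of bootstrap 5%-95% quantiles per edge (per week)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    df = summaries_df.reset_index(drop=True)
    labels = [
        f"wk{int(r.week)} {r.node_a}--{r.node_b}" if "week" in df.columns
        else f"{r.node_a}--{r.node_b}"
        for r in df.itertuples()
    ]
    y = np.arange(len(df))
    ax.hlines(y, df["q05"], df["q95"], color="#555555")
    ax.plot(df["point_estimate"], y, "o", color="#c0392b", ms=4)
    ax.axvline(0.0, color="black", lw=0.6)
    ax.set_yticks(y, labels, fontsize=6)
    ax.set_xlabel("edge weight")
    ax.set_title("Bootstrap 5%-95% sampling intervals")
    return ax
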