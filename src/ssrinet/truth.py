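"""Ground-truth parameterisations for the synthetic trial generator.

A :class:`GroundTruth` bundles everything the generator needs: a sparse
positive-definite precision matrix ``Omega`` over 17 latent symptom
variables (its negated scaled off-diagonal is the partial-correlation
network), per-week treatment-effect vectors ``delta`` on the latent
scale (negative = symptom-lowering, i.e. beneficial; by default these
are the conditional/direct effects the network estimator targets, see
``injection``), discretisation
cut-points mapping latent values to ordinal item scores, the treatment
allocation probability, a per-week missingness schedule, and the trial
stratification (number of trials, between-trial intercept spread).

The ``paper_like`` scenario is calibrated so that the trajectory of the
treatment node's network edges and the symptom-symptom partial
correlations match the values reported for the pooled SSRI-trial
analyses: the treatment shift on depressed mood grows from -0.09 at
week 1 to -0.17 at week 6, psychic anxiety reaches -0.11 at week 6, the
detrimental shift on genital symptoms grows from +0.02 to +0.11, and the
shift on weight loss decays from +0.16 to +0.03; depressed mood and
psychic anxiety are partially correlated at 0.20, psychic anxiety with
agitation and somatic anxiety at 0.19.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .items import ItemSpec, hdrs_battery

#: Assessment weeks of the pooled trials (baseline plus five follow-ups).
WEEKS = (0, 1, 2, 3, 4, 6)
FOLLOWUP_WEEKS = (1, 2, 3, 4, 6)

SCENARIOS = ("paper_like", "null", "dense_random")

# Per-week fraction of patients with complete symptom data, as printed for
# the pooled sample (N relative to the 8255 baseline-complete patients).
_COMPLETENESS = {1: 0.913, 2: 0.825, 3: 0.691, 4: 0.753, 6: 0.589}

# Baseline ordinal mean (SD) targets per item, used to place cut-points.
_BASELINE_MOMENTS = {
    "depressed_mood": (2.8, 0.6),
    "psychic_anxiety": (2.2, 0.75),
    "guilt": (1.7, 0.7),
    "suicidal_thoughts": (1.1, 0.9),
    "loss_of_interest": (2.7, 0.6),
    "retardation": (1.1, 0.8),
    "agitation": (1.1, 0.85),
    "somatic_anxiety": (1.6, 0.8),
    "general_somatic": (1.7, 0.5),
    "genital": (1.3, 0.8),
    "hypochondriasis": (0.9, 0.8),
    "gastrointestinal": (0.6, 0.7),
    "weight_loss": (0.3, 0.6),
    "insomnia_early": (1.2, 0.8),
    "insomnia_middle": (1.35, 0.75),
    "insomnia_late": (1.2, 0.8),
    "lack_of_insight": (0.2, 0.4),
}

# Sparse partial-correlation network of the paper_like scenario.  Affective
# symptoms are the hub: mood connects to psychic anxiety and the four
# cognitive items, psychic anxiety to the two anxiety-adjacent arousal
# items; weaker within-cluster links close the graph.
_PAPER_LIKE_PARTIALS = {
    ("depressed_mood", "psychic_anxiety"): 0.20,
    ("depressed_mood", "guilt"): 0.20,
    ("depressed_mood", "suicidal_thoughts"): 0.20,
    ("depressed_mood", "loss_of_interest"): 0.31,
    ("depressed_mood", "retardation"): 0.22,
    ("depressed_mood", "genital"): 0.10,
    ("psychic_anxiety", "guilt"): 0.12,
    ("psychic_anxiety", "loss_of_interest"): 0.10,
    ("psychic_anxiety", "agitation"): 0.19,
    ("psychic_anxiety", "somatic_anxiety"): 0.19,
    ("guilt", "suicidal_thoughts"): 0.15,
    ("loss_of_interest", "retardation"): 0.12,
    ("agitation", "somatic_anxiety"): 0.15,
    ("somatic_anxiety", "general_somatic"): 0.15,
    ("general_somatic", "gastrointestinal"): 0.12,
    ("general_somatic", "weight_loss"): 0.10,
    ("hypochondriasis", "gastrointestinal"): 0.12,
    ("hypochondriasis", "lack_of_insight"): 0.10,
    ("insomnia_early", "insomnia_middle"): 0.25,
    ("insomnia_middle", "insomnia_late"): 0.25,
    ("insomnia_early", "insomnia_late"): 0.15,
}

# Anchors for the per-week treatment shift (latent standardised units);
# weeks between anchors are linearly interpolated, week 0 is zero by
# randomization.
_PAPER_LIKE_DELTA_ANCHORS = {
    "depressed_mood": {1: -0.09, 6: -0.17},
    "psychic_anxiety": {1: -0.04, 2: -0.09, 6: -0.11},
    "genital": {1: 0.02, 6: 0.11},
    "weight_loss": {1: 0.16, 6: 0.03},
}


def default_missing_schedule() -> dict[int, float]:
    """Per-week probability that a patient's whole assessment is absent.

    One minus the printed per-week completeness fractions; week 0 keeps a
    token 0.001 rate (99.9% of patients complete at baseline).  The
    schedule is non-monotone (week 3 is sparser than week 4), so
    missingness is applied independently per week rather than as dropout.
    """
    sched = {0: 0.001}
    sched.update({w: round(1.0 - f, 3) for w, f in _COMPLETENESS.items()})
    return sched


def interpolate_anchors(anchors: dict[int, float], weeks=FOLLOWUP_WEEKS) -> dict[int, float]:
    """Piecewise-linear interpolation of per-week values between anchors.

    Weeks before the first anchor take the first anchor's value; weeks
    after the last take the last's.
    """
    if not anchors:
        return {w: 0.0 for w in weeks}
    xs = sorted(anchors)
    ys = [anchors[x] for x in xs]
    return {w: float(np.interp(w, xs, ys)) for w in weeks}


def _cutpoints_for(item: ItemSpec, latent_sd: float) -> np.ndarray:
    """Ascending latent thresholds whose implied ordinal distribution
    matches the item's baseline mean/SD targets (a discretised normal)."""
    m, s = _BASELINE_MOMENTS[item.name]
    qs = norm.cdf((np.arange(1, item.scale_max + 1) - 0.5 - m) / s)
    qs = np.clip(qs, 1e-5, 1 - 1e-5)
    cuts = latent_sd * norm.ppf(qs)
    # qs is already nondecreasing; enforce strict increase for degenerate tails
    for k in range(1, len(cuts)):
        if cuts[k] <= cuts[k - 1]:
            cuts[k] = cuts[k - 1] + 1e-6
    return cuts


@dataclass
class GroundTruth:
    """Generator parameters for one synthetic-trial scenario."""

    items: list[ItemSpec]
    Omega: np.ndarray
    delta: dict[int, np.ndarray]
    mu: np.ndarray
    cutpoints: list[np.ndarray]
    p_treat: float = 0.686  # 5424 SSRI / 7909 analysed patients
    missing_rate: dict[int, float] = field(default_factory=default_missing_schedule)
    n_trials: int = 28
    trial_shift_sd: float = 0.15
    scenario: str = "custom"
    #: how delta enters the latent means: "conditional" (default) injects the
    #: marginal shift Sigma @ diag(Omega) @ delta so that the conditional
    #: (direct, network-estimand) treatment effect per symptom equals delta
    #: exactly; "marginal" injects delta as the raw arm mean-difference.
    injection: str = "conditional"

    def __post_init__(self) -> None:
        self.Omega = np.asarray(self.Omega, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.delta = {int(w): np.asarray(d, dtype=float) for w, d in self.delta.items()}
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        p = len(self.items)
        if self.Omega.shape != (p, p):
            raise ValueError("Omega shape does not match the item battery")
        if not np.allclose(self.Omega, self.Omega.T):
            raise ValueError("Omega must be symmetric")
        if np.linalg.eigvalsh(self.Omega).min() <= 0:
            raise ValueError("Omega must be positive definite")
        if 0 in self.delta and np.any(self.delta[0] != 0):
            raise ValueError("delta at week 0 must be zero (randomization)")
        for w, d in self.delta.items():
            if d.shape != (p,):
                raise ValueError(f"delta[{w}] must have length {p}")
        if not 0 < self.p_treat < 1:
            raise ValueError("p_treat must lie in (0, 1)")
        for w, r in self.missing_rate.items():
            if not 0 <= r < 1:
                raise ValueError(f"missing_rate[{w}] outside [0, 1)")
        if len(self.cutpoints) != p:
            raise ValueError("one cut-point vector per item required")
        for it, cuts in zip(self.items, self.cutpoints):
            cuts = np.asarray(cuts, float)
            if len(cuts) != it.scale_max:
                raise ValueError(f"{it.name}: expected {it.scale_max} cut-points")
            if np.any(np.diff(cuts) <= 0):
                raise ValueError(f"{it.name}: cut-points must be strictly increasing")
        if self.injection not in ("conditional", "marginal"):
            raise ValueError(f"unknown injection mode {self.injection!r}")

    # -- derived quantities ----------------------------------------------
    @property
    def item_names(self) -> list[str]:
        return [it.name for it in self.items]

    @property
    def Sigma(self) -> np.ndarray:
        """Latent covariance (inverse precision)."""
        return np.linalg.inv(self.Omega)

    def partial_correlations(self) -> np.ndarray:
        """Partial-correlation matrix implied by Omega (unit diagonal)."""
        d = 1.0 / np.sqrt(np.diag(self.Omega))
        pc = -self.Omega * np.outer(d, d)
        np.fill_diagonal(pc, 1.0)
        return pc

    def marginal_shift(self, week: int) -> np.ndarray:
        """Latent mean-shift of the active arm actually injected at a week.

        Under ``conditional`` injection this is
        ``Sigma @ diag(Omega) @ delta``, chosen so that the conditional
        treatment coefficient of each symptom given all others equals
        ``delta`` exactly; under ``marginal`` injection it is ``delta``
        itself.
        """
        d = self.delta.get(week)
        if d is None:
            raise KeyError(f"no delta stored for week {week}")
        if self.injection == "marginal":
            return d
        return self.Sigma @ (np.diag(self.Omega) * d)

    def implied_direct_effects(self, week: int) -> np.ndarray:
        """Conditional (direct) treatment coefficient per symptom.

        Regressing one symptom on treatment and all other symptoms has
        treatment coefficient ``(Omega @ m)_j / Omega_jj`` where ``m``
        is the injected marginal shift.  This is the generator-side
        analogue of the estimated treatment-symptom edge, and is the
        reference for deciding which treatment edges are truly absent.
        Under ``conditional`` injection it equals ``delta`` exactly.
        """
        m = self.marginal_shift(week)
        return self.Omega @ m / np.diag(self.Omega)

    def null_treatment_items(self, week: int, tol: float = 5e-3) -> list[str]:
        """Items whose implied direct treatment effect is (numerically) zero."""
        eff = self.implied_direct_effects(week)
        return [n for n, e in zip(self.item_names, eff) if abs(e) < tol]

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "scenario": self.scenario,
            "items": [
                {"name": it.name, "category": it.category, "scale_max": it.scale_max}
                for it in self.items
            ],
            "Omega": self.Omega.tolist(),
            "delta": {str(w): d.tolist() for w, d in self.delta.items()},
            "mu": self.mu.tolist(),
            "cutpoints": [np.asarray(c, float).tolist() for c in self.cutpoints],
            "p_treat": self.p_treat,
            "missing_rate": {str(w): r for w, r in self.missing_rate.items()},
            "n_trials": self.n_trials,
            "trial_shift_sd": self.trial_shift_sd,
            "injection": self.injection,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            items=[ItemSpec(**d) for d in payload["items"]],
            Omega=np.asarray(payload["Omega"], float),
            delta={int(w): np.asarray(v, float) for w, v in payload["delta"].items()},
            mu=np.asarray(payload["mu"], float),
            cutpoints=[np.asarray(c, float) for c in payload["cutpoints"]],
            p_treat=payload["p_treat"],
            missing_rate={int(w): float(r) for w, r in payload["missing_rate"].items()},
            n_trials=payload["n_trials"],
            trial_shift_sd=payload["trial_shift_sd"],
            scenario=payload.get("scenario", "custom"),
            injection=payload.get("injection", "conditional"),
        )


def _paper_like_omega(items: list[ItemSpec]) -> np.ndarray:
    ix = {it.name: i for i, it in enumerate(items)}
    P = np.zeros((len(items), len(items)))
    for (a, b), v in _PAPER_LIKE_PARTIALS.items():
        P[ix[a], ix[b]] = P[ix[b], ix[a]] = v
    return np.eye(len(items)) - P


def _delta_map(items: list[ItemSpec], anchors_by_item: dict[str, dict[int, float]]) -> dict[int, np.ndarray]:
    ix = {it.name: i for i, it in enumerate(items)}
    delta = {w: np.zeros(len(items)) for w in WEEKS}
    for name, anchors in anchors_by_item.items():
        per_week = interpolate_anchors(anchors)
        for w, v in per_week.items():
            delta[w][ix[name]] = v
    delta[0] = np.zeros(len(items))
    return delta


def _dense_random_omega(p: int, seed: int = 20230121, density: float = 0.15) -> np.ndarray:
    """Random sparse positive-definite precision matrix (fixed seed)."""
    rng = np.random.default_rng(seed)
    P = np.zeros((p, p))
    for j in range(p):
        for k in range(j + 1, p):
            if rng.random() < density:
                P[j, k] = P[k, j] = rng.uniform(0.1, 0.3) * rng.choice([-1.0, 1.0])
    Om = np.eye(p) - P
    # shrink off-diagonals until comfortably positive definite
    while np.linalg.eigvalsh(Om).min() < 0.05:
        P *= 0.9
        Om = np.eye(p) - P
    return Om


def make_ground_truth(scenario: str = "paper_like", overrides: dict | None = None) -> GroundTruth:
    """Build a validated :class:`GroundTruth` for a named scenario.

    ``paper_like`` encodes the printed direct-effect trajectories and
    symptom-symptom partial correlations; ``null`` has no treatment
    effect and an identity precision (independent symptoms);
    ``dense_random`` draws a random sparse positive-definite precision
    from a fixed seed with no treatment effect.  ``overrides`` may
    replace any declared field (e.g. ``missing_rate``, ``p_treat``,
    ``trial_shift_sd``, ``Omega``) after scenario construction; the
    result is re-validated.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    items = hdrs_battery()
    p = len(items)
    if scenario == "paper_like":
        Omega = _paper_like_omega(items)
        delta = _delta_map(items, _PAPER_LIKE_DELTA_ANCHORS)
    elif scenario == "null":
        Omega = np.eye(p)
        delta = {w: np.zeros(p) for w in WEEKS}
    else:  # dense_random
        Omega = _dense_random_omega(p)
        delta = {w: np.zeros(p) for w in WEEKS}

    latent_sd = np.sqrt(np.diag(np.linalg.inv(Omega)))
    cutpoints = [_cutpoints_for(it, latent_sd[i]) for i, it in enumerate(items)]
    kwargs = dict(
        items=items,
        Omega=Omega,
        delta=delta,
        mu=np.zeros(p),
        cutpoints=cutpoints,
        scenario=scenario,
    )
    if overrides:
        allowed = {
            "Omega", "delta", "mu", "cutpoints", "p_treat", "missing_rate",
            "n_trials", "trial_shift_sd", "items", "injection",
        }
        unknown = set(overrides) - allowed
        if unknown:
            raise ValueError(f"unknown override field(s): {sorted(unknown)}")
        kwargs.update(overrides)
    return GroundTruth(**kwargs)
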