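"""End-to-end pipeline orchestration.

``run_pipeline`` executes the full analysis sequence on simulated or
loaded data: baseline table, weekly networks, direct/indirect effects,
cross-week stability correlations, overall effects, the direct-vs-
overall comparison, and (optionally) bootstrap edge accuracy and
covariate-adjusted sensitivity networks.  Every artifact is written
under the run directory together with a manifest (config, hash, seeds,
library versions) and a stage log; outputs are a pure function of
(data/scenario, config).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import io
from .bootstrap import summaries_frame
from .config import RunConfig
from .effects import baseline_table, direct_vs_overall, overall_effects
from .pipeline import (adjusted_networks, direct_effects,
                       fit_weekly_networks, indirect_effects,
                       stability_correlation)
from .seeds import derive_seed
from .simulate import simulate_trial
from .truth import make_ground_truth

logger = logging.getLogger(__name__)


def _versions() -> dict[str, str]:
    import matplotlib
    import networkx
    import numba
    import numpy
    import pandas
    import scipy

    from . import __version__
    return {
        "ssrinet": __version__,
        "numpy": numpy.__version__, "scipy": scipy.__version__,
        "pandas": pandas.__version__, "numba": numba.__version__,
        "networkx": networkx.__version__, "matplotlib": matplotlib.__version__,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis and return the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    manifest: dict = {
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "versions": _versions(),
        "stages": {},
    }
    log_lines: list[str] = []

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception:
                log_lines.append(f"{name}: FAILED")
                log_path.write_text("\n".join(log_lines) + "\n")
                (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
                logger.exception("pipeline stage %r failed", name)
                raise
            dt = time.perf_counter() - t0
            manifest["stages"][name] = {"seconds": round(dt, 3)}
            log_lines.append(f"{name}: ok ({dt:.2f}s)")
            return out
        return deco

    # --- data -----------------------------------------------------------
    def load():
        if config.input_csv:
            return io.read_trial_csv(config.input_csv, latent=config.latent)
        gt = make_ground_truth(config.scenario or "paper_like")
        gt.to_json(outdir / "scenario.json")
        ds = simulate_trial(gt, config.n_patients, weeks=[0] + list(config.weeks),
                            seed=derive_seed(config.seed, "simulate"),
                            latent_only=config.latent)
        io.write_trial_csv(ds, outdir / "trial_data.csv")
        return ds
    data = stage("data")(load)

    def baseline():
        table = baseline_table(data)
        table.to_csv(outdir / "baseline_table.csv", index=False)
        return table
    stage("baseline_table")(baseline)

    def networks():
        models = fit_weekly_networks(data, config.weeks, config.mgm_config(),
                                     seed=derive_seed(config.seed, "networks"))
        for w, res in models.items():
            io.write_edgelist_csv(res, outdir / f"network_week{w}_edges.csv")
            io.write_graphml(res, outdir / f"network_week{w}.graphml")
            io.write_network_json(res, outdir / f"network_week{w}.json")
        manifest["networks"] = {int(w): {"n": res.n_samples} for w, res in models.items()}
        return models
    models = stage("weekly_networks")(networks)

    def direct():
        traj = direct_effects(models)
        traj.to_csv(outdir / "direct_effects.csv")
        return traj
    traj = stage("direct_effects")(direct)

    def indirect():
        frames = []
        for w, res in models.items():
            t = indirect_effects(res)
            t.insert(0, "week", w)
            if not t.empty:
                frames.append(t)
        if frames:
            table = pd.concat(frames, ignore_index=True)
        else:
            table = pd.DataFrame(columns=["week", "mediator", "target",
                                          "treatment_edge", "mediator_target_edge",
                                          "product"])
        table.to_csv(outdir / "indirect_effects.csv", index=False)
        return table
    stage("indirect_effects")(indirect)

    def stability():
        if len(config.weeks) < 2:
            return {}
        corr = stability_correlation(traj)
        frame = pd.DataFrame(
            [{"week_a": a, "week_b": b, "pearson_r": r} for (a, b), r in corr.items()]
        )
        frame.to_csv(outdir / "stability_correlations.csv", index=False)
        return corr
    stage("stability")(stability)

    def overall():
        table = overall_effects(data, config.weeks)
        table.to_csv(outdir / "overall_effects.csv", index=False)
        return table
    eff = stage("overall_effects")(overall)

    def compare():
        table = direct_vs_overall(traj, eff)
        table.to_csv(outdir / "direct_vs_overall.csv", index=False)
        return table
    stage("direct_vs_overall")(compare)

    if config.bootstrap_B > 0:
        def boot():
            frames = []
            for w in (config.bootstrap_weeks or config.weeks):
                res = models[int(w)]
                summ = res.bootstrap(
                    B=config.bootstrap_B,
                    seed=derive_seed(config.seed, "bootstrap", w),
                    reselect_lambda=config.bootstrap_reselect,
                )
                frame = summaries_frame(summ)
                frame.insert(0, "week", int(w))
                frames.append(frame)
            table = pd.concat(frames, ignore_index=True)
            table.to_csv(outdir / "bootstrap_summaries.csv", index=False)
            return table
        stage("bootstrap")(boot)

    if config.covariates:
        def sensitivity():
            adj = adjusted_networks(data, config.weeks, config.covariates,
                                    config.mgm_config(),
                                    seed=derive_seed(config.seed, "adjusted"))
            frames = []
            for w, entry in adj.items():
                cmp_ = entry["comparison"].reset_index(names="symptom")
                cmp_.insert(0, "week", w)
                frames.append(cmp_)
            table = pd.concat(frames, ignore_index=True)
            table.to_csv(outdir / "adjusted_vs_unadjusted.csv", index=False)
            return table
        stage("sensitivity")(sensitivity)

    if config.plots:
        def plots():
            from .plotting import plot_network, plot_trajectory
            import matplotlib
            matplotlib.use("Agg", force=False)
            import matplotlib.pyplot as plt
            ax = plot_trajectory(traj, items=data.items)
            ax.figure.savefig(outdir / "direct_effect_trajectory.svg")
            plt.close(ax.figure)
            ov = traj.values.copy()
            for w, res in models.items():
                ax = plot_network(res, items=data.items)
                ax.figure.savefig(outdir / f"network_week{w}.svg")
                plt.close(ax.figure)
            return ov
        stage("plots")(plots)

    log_path.write_text("\n".join(log_lines) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
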