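# ssrinet

Symptom-network analysis of randomized, placebo-controlled SSRI trials.

Conventional trial analyses sum the 17 Hamilton Depression Rating Scale
(HDRS) items into one score and ask whether the drug beats placebo
overall. That hides *which* symptoms a drug moves directly and which
only change because other symptoms changed. `ssrinet` implements the
network alternative for researchers in psychiatric epidemiology and
clinical pharmacology: at each follow-up week it estimates a **mixed
graphical model** over a binary treatment node and the 17 symptom
nodes, reads treatment–symptom edges as **direct effects** and
symptom–symptom paths as **indirect effects**, and runs the classical
t-test / Cohen's d track alongside for contrast.

The estimator is nodewise l1-regularized regression (neighborhood
selection): symptom nodes by gaussian lasso, the treatment node by
penalized logistic regression, each node's penalty chosen by 10-fold
cross-validation, and the pairwise coefficients combined under the AND
rule into a symmetric, signed, standardized edge-weight matrix. Edge
accuracy is assessed by a full-procedure nonparametric bootstrap
(percentile 5%/95% intervals), and sensitivity networks adjust for
trial membership, age, or sex as penalized predictor blocks.

Because the underlying patient-level trial data are proprietary, the
package ships a calibrated synthetic trial generator (latent Gaussian
graphical model + per-item ordinal cut-points + per-week treatment
shifts + realistic per-week missingness) so that the entire pipeline is
testable and demonstrable end to end. See `docs/methods.md` for the
model, the generator's calibration, and its limitations.

## Worked example

```python
from ssrinet import (make_ground_truth, simulate_trial, fit_weekly_networks,
                     direct_effects, stability_correlation, overall_effects)

gt = make_ground_truth("paper_like")          # calibrated scenario
ds = simulate_trial(gt, 5000, seed=1, latent_only=True)

models = fit_weekly_networks(ds, weeks=[1, 6], seed=1)
traj = direct_effects(models)
print(traj.values.round(3)[["depressed_mood", "psychic_anxiety",
                            "genital", "weight_loss"]])
```

```
      depressed_mood  psychic_anxiety  genital  weight_loss
week
1             -0.061            0.000    0.000        0.125
6             -0.134           -0.041    0.033        0.000
```

Read: by week 6 the SSRI arm shows a direct beneficial effect on
depressed mood of −0.134 SD (conditional on all other symptoms) that
grew from −0.061 at week 1, a direct beneficial effect on psychic
anxiety that was absent at week 1, an emerging *detrimental* direct
effect on genital symptoms (a side effect), and a weight-loss effect
that was strong at week 1 (+0.125) and has faded by week 6. The
generator's true week-6 direct effects for these four edges are −0.17,
−0.11, +0.11 and +0.03; the default scenario also applies the per-week
missingness schedule, so the week-6 network is fitted on the ~59%
complete cases (n = 2829 here), which is why the weaker edges are
shrunk harder than in a complete-data run.

Each fitted week is a results object:

```python
res = models[6]
print(res.summary())            # edge table, n, rule, per-node lambdas
res.treatment_row()             # the direct-effect vector
res.bootstrap(B=100, seed=1)    # per-edge percentile intervals
res.to_graphml("week6.graphml")
```

The same workflow is scriptable from the shell:

```sh
ssrinet simulate --out trial.csv --scenario paper_like --n-patients 2000 --seed 1
ssrinet fit trial.csv --week 6 --out-prefix week6
ssrinet pipeline --scenario paper_like --n-patients 2000 --seed 1 --outdir run/
ssrinet report run/
```

`pipeline` writes the baseline comparison table, per-week networks
(edge-list CSV / GraphML / JSON), the direct-effect trajectory, the
indirect-effect 2-path table, cross-week stability correlations, the
overall-effect (Cohen's d) table, the direct-vs-overall comparison,
optional bootstrap summaries and adjusted networks, figures, a stage
log, and a manifest with the config hash — all byte-reproducible from
(scenario, seed, config).

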