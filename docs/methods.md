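# Methods

## The analysis

`ssrinet` implements an item-level network analysis of randomized,
placebo-controlled antidepressant (SSRI) trials. Instead of a summed
depression score, each of the 17 Hamilton Depression Rating Scale
(HDRS) items is a variable, and at each follow-up assessment (weeks 1,
2, 3, 4, 6) a **mixed graphical model** is estimated over one binary
treatment node (SSRI vs placebo) and the 17 continuous symptom nodes.
Edges between the treatment node and a symptom are **direct treatment
effects** — the arm difference on that symptom conditional on all other
symptoms; symptom–symptom edges route **indirect effects**. A parallel
classical track computes per-week **overall effects** (independent
t-tests and Cohen's d), and the contrast between the two tracks is what
identifies symptoms whose change is mediated rather than direct.

### Estimation

The network is estimated by nodewise neighborhood regression:

* each symptom node *j* is regressed on the treatment indicator and the
  other 16 symptoms with an l1 (lasso) penalty,
  `(1/2n) Σ (y_i − β0 − x_i'β)² + λ‖β‖₁`;
* the treatment node is regressed on all symptoms by l1-penalized
  logistic regression, `(1/n) Σ log(1+exp((1−2y_i)(β0+x_i'β))) + λ‖β‖₁`;
* intercepts are unpenalized; each node's λ is chosen by 10-fold
  cross-validation (held-out MSE / mean deviance), taking the
  loss-minimizing λ with ties broken toward the sparser model (a 1-SE
  policy is available by flag);
* the two coefficients of a node pair are aggregated under the **AND
  rule** (edge present only if both are nonzero; OR available), with
  magnitude `(|a|+|b|)/2` and their shared sign; disagreeing signs keep
  the magnitude, mark the sign undefined and log a warning.

Solvers are written in-package: cyclic coordinate descent on the Gram
matrix for the gaussian problem (path cost independent of n once
`X'X/n` is formed) and a majorize–minimize scheme with the logistic
curvature bound 1/4 for the binomial problem, both numba-jitted and
warm-started along a 50-point log-spaced grid from λ_max down to
1e-4·λ_max. Every full-data refit carries a KKT subgradient
certificate (tolerance 1e-6); coordinate updates iterate to 1e-10 and
the logistic outer loop to a relative objective change of 1e-11
(full fits) / 1e-9 (CV path fits).

Continuous columns are standardized to mean 0, SD 1 (denominator n−1)
per week. Binary columns (treatment, sex, trial-id dummies) are kept
0/1 at the interface but put on unit-SD scale internally for
penalization — the behaviour of glmnet-family estimators — and
back-transformed, so a treatment–symptom edge reads "per-SD-of-symptom
change for receiving SSRI". Without this, the penalty on the
treatment coefficient is effectively inflated by 1/SD(arm) ≈ 2.2 and
moderate true edges (≈0.1) are missed at realistic sample sizes.

Covariate adjustment (trial-id, age, sex) follows the predictor-block
convention: covariates enter every nodewise regression as penalized
predictors (trial-id one-hot encoded) but are not reported as network
nodes. This reproduces the confound-removal function of a joint model
without multinomial group-lasso machinery; it is an approximation and
is labelled as such.

### Derived quantities

* **Direct-effect trajectory** — the signed treatment-edge row per week
  (negative = beneficial). Cross-week stability is summarized by
  Pearson correlations between consecutive weeks' 17-vectors (zeros
  included).
* **Indirect-effect table** — all treatment → mediator → target 2-paths
  with both edges nonzero, scored by the product of the two edge
  weights. This is a descriptive reading of the graph, not a formal
  mediation test.
* **Direct vs overall comparison** — per week × symptom, the direct
  edge next to Cohen's d, flagging `indirect_dominant` (|d| ≥ 0.15 with
  no direct edge) and `direct_dominant` (|edge| ≥ 0.15 with |d| < 0.15).
* **Bootstrap edge accuracy** — row resampling at the original n, the
  whole estimation re-run per replicate (CV re-selected by default;
  freezing available), type-7 empirical 5%/95% quantiles per edge and a
  boundary-inclusive `includes_zero` flag (q05 ≤ 0 ≤ q95).
* **Classical track** — pooled-variance Student t-tests (Welch by
  flag), Cohen's d with the pooled-SD denominator (sign SSRI −
  placebo), Pearson chi-square without continuity correction for sex,
  and a Bonferroni threshold of 0.05/17 ≈ 0.003 for the 17 baseline
  symptom comparisons.

Weeks are analysed independently (no smoothing or parameter sharing),
each on its own complete cases: a patient contributes to week w iff all
17 items are present at week w.

## The synthetic trial generator

Patient-level data from the underlying trial programme are proprietary,
so the package ships a generator that emulates their structure and
serves as ground truth for every test.

Latent symptom vectors are multivariate normal with a sparse
positive-definite precision matrix Ω; ordinal scores arise by
thresholding each latent variable at per-item cut-points (hard-clipped
at the extremes). The `paper_like` scenario encodes:

* the reported partial correlations (mood–psychic anxiety 0.20,
  psychic anxiety–agitation and –somatic anxiety 0.19, mood–cognitive
  links in the 0.20–0.31 range, plus plausible weaker within-cluster
  links; smallest eigenvalue of Ω ≈ 0.35);
* per-week direct treatment effects δ stored exactly at the reported
  anchors — depressed mood −0.09 (week 1) → −0.17 (week 6), psychic
  anxiety −0.04 → −0.09 (week 2) → −0.11, genital symptoms +0.02 →
  +0.11, weight loss +0.16 → +0.03 — linearly interpolated at
  unlisted weeks, zero at baseline (randomization);
* a 0.686 active-arm allocation (the analysed 2:1-ish pooled ratio), 28
  trial strata with Normal(0, 0.15²) intercepts, age ~ Normal(44,
  14.5²) truncated to [18, 90], sex ~ Bernoulli(0.595);
* cut-points placed so baseline ordinal means/SDs approximate the
  reported baseline table (e.g. depressed mood ≈ 2.8 (0.6));
* per-week assessment-level missingness equal to one minus the reported
  completeness fractions ({1: 0.087, 2: 0.175, 3: 0.309, 4: 0.247,
  6: 0.411}, week 0: 0.001), applied independently per week because the
  reported per-week Ns are non-monotone. Missingness is completely at
  random; the real trials' missingness mechanism is unknown, and an
  outcome-dependent mode is deliberately not a default.

**Injection semantics.** By default δ is injected *conditionally*: the
active arm's latent mean shift is `m = Σ·diag(Ω)·δ` (Σ = Ω⁻¹), the
unique shift for which the conditional (direct, network-estimand)
treatment effect of each symptom equals δ exactly. This makes the
stored anchors the literal recovery targets and keeps "symptoms with no
direct effect" exactly null conditionally, while their marginal means
still move through the network (the indirect pathway). A `marginal`
mode (inject δ as the raw arm mean-difference) is available; under it
the implied direct effects attenuate (e.g. psychic anxiety −0.11 →
−0.076 via the mood link), which blurs the recovery targets. At week 1
the two modes are statistically indistinguishable at simulation sizes.

`null` (identity Ω, δ ≡ 0) and `dense_random` (seeded random sparse
positive-definite Ω, δ ≡ 0) scenarios support false-positive and
structure-only checks.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: ordinal items are treated as continuous by
the estimator (the generator's `latent_only` mode exists precisely to
separate solver correctness from discretisation bias); missingness is
MCAR; there is no rater model, no drug-specific heterogeneity, no
within-patient serial correlation across weeks (each week draws fresh
noise, as the per-week cross-sectional analysis assumes); and marginal
effect sizes are those implied by the conditional calibration (mood d ≈
−0.27 at week 6 rather than the reported −0.40, since a single-snapshot
Gaussian model cannot reproduce conditional and marginal magnitudes
simultaneously).

## Numerical and design choices

* λ grid: 50 points, min ratio 1e-4; grid anchored at the exact
  stationarity bound λ_max = max_j |x_j'(y−ȳ)|/n.
* CV folds: seeded permutation chunking; binomial folds with a constant
  training response are re-drawn from a derived seed (≤10 attempts).
* Tie-breaks: equal CV loss → larger (sparser) λ; deterministic.
* Every stage seed derives from a master seed plus a CRC-tagged stage
  name, so any stage can be reproduced in isolation and full pipeline
  outputs are byte-identical across reruns of the same configuration.
* Bootstrap replicate failures are recorded and skipped; >20% failures
  is an error. Degenerate inputs (zero-variance columns, single-arm
  data, constant binary response) raise named validation errors.
* Quantiles are type-7 (linear interpolation) throughout.
* Problem sizes in the shipped experiments: recovery and headline runs
  use n = 5000 per week with 20 replicate seeds, null-control networks
  n = 2000, family-wise-error replicates n = 400 × 200, bootstrap runs
  n = 1000 with B = 100 — sizes at which each check's target quantity
  is well-resolved while the whole suite stays desk-scale.

## Known limitations

* The AND-rule lasso edge has point mass at zero; at small n this
  makes boundary-inclusive bootstrap intervals conservative (at
  n = 1000 the treatment–mood 5–95% interval still touches zero in most
  runs even though the edge itself is detected), so interval-based
  claims should use the original-study scale, not reduced sizes.
* Indirect-effect products are descriptive graph summaries; no
  mediation inference is implied.
* Trial-id adjustment by one-hot predictor blocks is an approximation
  to a categorical node.
* Min-CV λ selection overselects in single regressions on pure noise;
  network-level sparsity is restored by the AND rule (and the 1-SE
  policy is available where single-fit sparsity matters).
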