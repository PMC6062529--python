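# Methods

## The optimization problem

A pipeline P = {I(θ_I), F(θ_F), M(θ_M), C} chains an imputer, a feature
processor, a classifier and a calibrator; its hyper-parameters θ live in the
box/level domains declared by the registry. The objective is the empirical
clinical utility U(P(θ), D) = ½·(AUC-PR + average precision), estimated by
stratified k-fold cross-validation with folds fixed per run so utilities are
comparable across pipelines. AUC-PR integrates the precision-recall curve by
the trapezoidal rule after keeping the maximum precision per distinct recall
and anchoring at (0, first precision); average precision is the
recall-increment-weighted mean of precisions over descending thresholds with
tied scores grouped. The two are numerically close on well-behaved curves,
and reporting their mean hedges against the trapezoid's optimism on jagged
ones.

## Decoupled Gaussian-process search

The search assumes imputation and calibration quality are approximately
independent of the (classifier, processor) choice, so the utility splits into
three additive terms, each modeled by its own zero-mean GP (observations are
centered before solving, so an empty surrogate predicts 0 with the prior
standard deviation and interpolates noise-free observations exactly):

* Ũ(M, F): the joint classifier × processor surrogate, the main search
  space including all hyper-parameters of both stages;
* Ũ_I(I): imputer utility, scored as the CV utility of the imputer ahead of
  a fixed reference pipeline (identity processing + logistic regression, no
  calibration);
* Ũ_c(C): calibrator utility, scored as 1 − (CV Brier score) of the
  calibrated reference pipeline — calibration affects score placement, not
  ranking, so a ranking metric cannot distinguish calibrators.

The reference-pipeline scoring of Ũ_I and Ũ_c is this package's own
concretization; the decoupling assumption itself licenses scoring a stage
against any fixed completion.

Points are encoded as (categorical component indices, continuous
hyper-parameters normalized to [0, 1], log scale where the domain is
log-flagged); hyper-parameters of components not selected by a point are
imputed at the domain midpoint 0.5 so distances across components remain
defined. The kernel is signal_var × Matérn-5/2(‖Δcont‖/ℓ) ×
exp(−γ·#categorical disagreements) — a product of valid kernels, hence
positive semidefinite; Matérn-5/2 gives twice-differentiable sample paths,
the conventional choice for hyper-parameter response surfaces.

Each iteration maximizes the UCB acquisition μ + κσ over a random candidate
pool (the space is mostly categorical, so gradient ascent buys little),
evaluates all three utilities, and updates the posteriors. Component fit
failures are caught and recorded as utility 0 rather than aborting the run.

Defaults and rationale:

| parameter | default | notes |
|---|---|---|
| budget | 200 iterations | matches the study-scale search length |
| κ (UCB) | 2.0 | standard exploration weight; configurable |
| initial design | 5 random configs | seeds the GP before acquisition takes over |
| candidate pool | 500 per proposal | argmax quality saturates well below this for these space sizes |
| kernel refit | every 5 iterations | L-BFGS-B on log(ℓ, γ, signal, noise) by marginal likelihood |
| jitter | 1e-8 on the Gram diagonal | escalated to 1e-6 once if factorization fails |
| inner CV | 3 folds | evaluation noise trades off against per-iteration cost |
| outer CV report | 10 folds | matches the study's validation protocol |

## Ensemble

Explored (M, F) points (deduplicated across re-examinations) receive weights
equal to the posterior probability of having the highest utility, estimated
from draws of the *joint* GP posterior — the probability-of-best event is
joint, and correlated utilities materially change it relative to independent
marginals. Exact ties in a draw split weight equally. Members below 0.01 are
pruned, weights renormalized (if everything is pruned the single best member
survives with weight 1), and survivors are refit on the full dataset with the
imputer and calibrator fixed at their decoupled posterior-mean optima.
Weights are computed from the CV-era posterior, before the refit: the refit
changes the fitted functions, not the evidence about relative utility.
Prediction is the weighted arithmetic mean of member risk scores, clipped to
[0, 1].

Calibrators are fit on an internal stratified 20% split held out from the
classifier; calibrating on the classifier's own training scores overfits the
Brier score.

## Interpreter

Risk scores are assigned to strata (half-open intervals, last closed;
default breakpoints 0.05 / 0.33 / 0.5 labeled low / moderate / high / very
high). Continuous covariates are discretized by Fayyad–Irani recursive
entropy splitting under the MDL acceptance bound
gain > (log₂(N−1) + log₂(3^k−2) − k·E + k₁·E₁ + k₂·E₂)/N, with per-column
forced cuts overriding the automatic ones (FEV₁% at 30 in the CLI).
Discretization is fit on the data being explained — the interpreter is
descriptive, not predictive, so a held-out split would only blur it.

Rule mining is greedy: per risk group meeting the support floor, the
antecedent grows one condition at a time, always adding the condition of
highest confidence (ties: higher standard support, then lexicographic), up
to 3 conditions — emitted as soon as both thresholds hold on the full
dataset, which also keeps subsumed longer rules out. Covered rows are then
removed and mining repeats (sequential covering), so a group can yield
several rules. Following the source convention, *support* is the prevalence
of the consequent risk group — rule-independent within a group; since that
convention is unusual, the standard antecedent∧consequent support is reported
alongside. Confidence with no matching rows is reported missing, never 0.

## Synthetic registry generator

One latent severity factor Z ~ N(0,1) per patient drives everything: a
declining FEV₁% trajectory (baseline 70 − 22Z with faster decline for
Z > 0), anthropometrics, Bernoulli comorbidity/treatment flags with log-odds
linear in Z, and the composite outcome with log-odds
a·Z + b·oxygen + c·1(FEV₁% < 30), the intercept calibrated by root finding so
the marginal prevalence matches the spec (default 9.4% at n = 4,064, the
study's cohort scale). An `exact_prevalence` mode replaces independent
Bernoulli outcomes with a Gumbel-top-k draw hitting round(n·prevalence)
events exactly, for reproducing printed selection flows. Oxygen therapy
carries an outcome effect beyond FEV₁ so that precision-oriented (AUC-PR)
variable importance can rank it above spirometry while AUC-ROC does not — a
single factor reproduces the heavy inter-correlation of real CF risk factors
cheaply. Missingness follows the published per-column rates (FEV₁ history
31.0/20.0/15.5/6.2/4.4%, anthropometrics 2.1/1.4/2.9%), MCAR by default or
severity-dependent MAR with the marginal rate preserved by a root-found
offset. Genotypes are drawn from a small pool of common CFTR mutations.

What the generator does *not* emulate: the full 115-variable covariate map,
center effects, informative loss to follow-up, longitudinal dynamics beyond
the FEV₁ block, and real feature-measurement error. Passing tests therefore
demonstrate that the machinery recovers structure it is pointed at — not
that real-registry accuracy figures would be reproduced.

## Numerical and convention choices

* UCB is maximized as μ + κσ: an optimistic bound is required when
  maximizing utility.
* Youden cutoff ties resolve to the lowest cutoff (favours sensitivity,
  matching the referral use-case); classification at cutoff c is score ≥ c,
  while the FEV₁ referral criterion is strictly FEV₁% < threshold.
* Confusion-matrix ratios with zero denominators are missing (NaN), not 0.
* Fisher's exact test is two-sided by the probability-mass convention;
  Mann-Whitney U uses exact enumeration for n_x·n_y ≤ 400 without ties, the
  tie-corrected normal approximation otherwise.
* The age filter defaults to ≥ 18 years with a configurable comparator.
* Cutoff tables target sensitivities rather than fixed cutoffs (smallest
  cutoff achieving at-least-target sensitivity), so models are compared at
  equal recall.
* All randomness flows from integer seeds; identical seeds reproduce every
  output byte-for-byte.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script runs use a reduced registry (3 imputers,
2 processors, 3 classifiers with trees capped at 200) with search budgets of
30–50 iterations and 3 inner folds, on cohorts of n = 4,064; planted-rule
mining uses n = 5,000 and Monte-Carlo weight checks 10⁶ draws. These sizes
give stable pass/fail behavior on a single CPU while exercising every code
path at the study's cohort scale.

## Known limitations

* The decoupling assumption is an approximation; an imputer that interacts
  strongly with a particular classifier will be scored through the reference
  pipeline only.
* One mixed-kernel GP covers the joint (M, F) space; per-classifier GPs are
  an equally admissible reading and may model sharply different
  hyper-parameter response surfaces better.
* Acquisition is optimized over a random pool, so in very large continuous
  domains the proposal is approximate.
* The interpreter's greedy growth has no optimality guarantee; it recovers
  planted conjunctions reliably but can emit negated-level ("other")
  conjunctions when strata are highly unbalanced.
* Survival-time outcomes, batch acquisition and meta-learning warm starts
  are out of scope.
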