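# Methods

## Problem setting

Case-control gene-expression studies of psychiatric disorders are
individually small and technically heterogeneous: cohort-specific (batch)
variation typically dwarfs the diagnostic signal, and models trained on one
cohort generalize poorly to others.  This package compares two strategies
for integrating several cohorts into one classifier:

* **single-task learning (STL)** — concatenate the cohorts and fit one
  model (lasso logistic regression, linear SVM, random forest);
* **multi-task learning (MTL)** — treat each cohort as a *task*, fit one
  weight vector per task jointly, and couple the tasks through a
  cross-task penalty.

All MTL formulations minimize the task-averaged logistic loss

    L(W, C) = sum_i (1/n_i) sum_j log(1 + exp(-Y_ij (X_ij W_i + C_i)))

over the p-by-t weight matrix `W` (column i belongs to cohort i) and
intercepts `C`, plus one of the penalties:

| tag   | penalty | effect |
|-------|---------|--------|
| NET   | `λ Σ_i ‖W_i − W̄‖²₂` (W̄ = across-task mean) | pulls every task toward a latent shared model, harmonizing both effect sizes and signs |
| SNET  | `λ(α · net-term + (1−α)‖W‖₁)` | sparse variant of NET |
| L21   | `λ Σ_g ‖W^g‖₂` over gene rows | selects or rejects each gene jointly for all tasks |
| EN    | `λ((1−α)‖W‖₂,₁ + α‖W‖²_F)` | L21 stabilized elastic-net style |
| TRACE | `λ‖W‖₊` (nuclear norm) | encourages a low-rank, clustered task structure |

Single-task lasso (`LR_L1`) is the t = 1 degenerate case of the same
objective, so STL and MTL losses are exactly comparable.

## Optimizer

All formulations are solved with a monotone FISTA (accelerated proximal
gradient with backtracking line search; initial step 1.0, halving factor
0.5, optimistic growth 1.2 between iterations).  Smooth terms — the loss,
the NET deviation penalty (gradient `2λ(W_k − W̄)`, which is exact because
deviations sum to zero across tasks), and EN's Frobenius term — enter the
gradient; the ℓ1, ℓ2,1 and nuclear penalties enter through their proximal
operators (soft-thresholding, row-wise group thresholding,
singular-value thresholding).  When the extrapolated candidate would raise
the objective, momentum is restarted and a plain proximal step is taken, so
the objective trace is non-increasing by construction.  Iteration stops at
a relative objective change below `tol` (default 1e-6) or `max_iter`
(default 2000); intercepts are never penalized; zeros produced by
thresholding are exact.  The solver is deterministic, so only data
generation, fold assignment and resampling consume seeds.

Default hyperparameter grids: λ = 10^(−6..2) step 1 for NET/SNET,
10^(−6..0) step 0.1 for L21/EN, 10^(−6..1) step 0.1 for TRACE,
10^(−10..1) step 0.5 for LR_L1; α = 0..1 step 0.1; SVM box constraint
C = 10^(−5..5) step 1.  CV ties prefer stronger regularization (larger λ,
smaller C) for reproducibility.  The desk-scale drivers use documented
subsets of these grids.

## Prediction and evaluation protocol

An MTL model scores a new sample with the across-task mean of
`sigmoid(x·W_i + C_i)` and assigns the case class when the probability
exceeds 0.5 (ties to control).  Generalizability is measured
*leave-dataset-out*: for cohorts D, every training subset d with
|d| = n_d ∈ {2,3,4} is fitted (hyperparameters by stratified 5-fold CV
inside d, folds stratified by cohort × diagnosis) and tested on each
held-out cohort separately.  During CV, MTL trains per-cohort on the
training folds and averages held-out per-cohort accuracies; STL pools
training folds and scores the pooled held-out folds — mirroring how each
family is deployed.  Repetitions re-randomize the CV folds only; the
repetition-level summary is the mean over subsets and test cohorts, with
the SE taken over repetition means.

## Robustness statistics

A model's *transcriptomic profile* is its signed per-gene coefficient
vector (for MTL, the row-wise mean of W; the random forest's unsigned
importances are excluded from profile comparisons).  Profiles are compared
by Pearson correlation over all genes.  From B stratified bootstrap
replicates (resampling subjects with replacement within cohort × diagnosis
cells, preserving cell sizes):

* **horizontal consistency** — mean pairwise correlation among profiles of
  all subsets of one size, per replicate (undefined at n_d = t, where only
  one subset exists);
* **vertical consistency** — mean correlation between the all-cohorts
  profile and each smaller-subset profile, per replicate;
* **stability** — mean pairwise correlation across replicates of one
  training subset;
* **success rate** — fraction of paired comparisons (paired by replicate
  for consistency, by subset for stability) where one algorithm strictly
  beats the other; ties count against the first algorithm.

Consistency is computed within replicates and summarized across them;
stability per subset across replicates.  Hyperparameters for robustness
fits are selected once on the original data (or pinned) and reused across
replicates — selection noise would otherwise be confounded with sampling
variability.

## Synthetic benchmark

The generator draws, for cohort i and subject j with diagnosis y ∈ {−1,+1}:

    x_j = b_i + y·w_i/2 + Γ z_j + ε_j,  ε_j ~ N(0, I_p)

`w_i = w* + δ_i`: a shared signature `w*` with entries ±β on a random
support of size s (zero elsewhere) plus per-cohort perturbations δ_i with
SD `sigma_task` on the support; `b_i`: per-cohort per-gene offsets with SD
`sigma_batch`; `Γ z_j`: global linear loadings of age, sex, PMI and pH.
The symmetric ±w/2 coding makes a logistic model with weights ∝ w_i
Bayes-optimal (accuracy Φ(‖w*‖/2) for the `w*` scorer), so recovery tests
are well-posed.

Defaults (five cohorts, p = 300, n = 60, s = 20, β = 0.8,
sigma_task = 0.3, sigma_batch = 2.0) encode the intended regime: each
signature gene shifts by under one noise SD while cohort offsets are more
than twice that, so cohort identity dominates raw expression — the
situation that motivates batch adjustment and cross-task coupling.  Cohort
covariate distributions (age means 40–75, PMI 5–40 h, pH ≈ 6.3,
male-skewed sex ratios) imitate post-mortem brain cohorts.  An imbalance
spec can shift case covariates and group sizes to create the confounding
that propensity matching must repair.

What the generator does **not** emulate: probe-level or platform-specific
artifacts, gene–gene correlation beyond the shared signature,
non-Gaussian expression noise, and nonlinear covariate effects.  Passing
tests therefore show that the algorithms behave correctly in the assumed
additive-Gaussian regime; they do not certify performance on real arrays.

## Preprocessing

Fixed order: probe collapsing (mean over rows sharing a gene symbol) →
common-gene intersection (sorted) → per-cohort 1:1 propensity matching →
column-wise concatenation → quantile normalization → batch/covariate
adjustment → split → per-cohort z-scoring (population SD; constant genes
zeroed with a warning).

*Matching.* The propensity is an unpenalized logistic regression of
diagnosis on sex, pH, age and PMI (standardized; pH dropped with a log
line when missing, constant covariates dropped with a warning).  Greedy
nearest-neighbor matching without replacement runs on the logit scale,
anchored on the **minority** diagnosis group in descending propensity
order (ties by sample ID).  Anchoring on the minority side matters: if the
scarce group is the pool, every anchor competes for it and the matched set
ends up containing the most extreme members of the majority group, which
can *increase* covariate imbalance; with minority anchors each one gets a
genuine nearest neighbor.  An optional caliper (in SDs of the logit,
default off) drops distant pairs.

*Batch adjustment.* A parametric empirical-Bayes location-scale adjuster
in the ComBat tradition: per-gene linear model on batch indicators plus
sex, pH, age, age², PMI (never diagnosis — the protected variable);
per-batch location/scale effects are shrunk toward across-gene priors
(normal for locations, inverse-gamma for scales, method-of-moments
hyperparameters, iterative joint posterior to 1e-6) and removed.  Unlike
the classical formulation, the fitted covariate contributions are removed
as well by default (`keep_covariates=True` restores them), since the
downstream learners should not be handed age or PMI signal.

## Numerical and design choices

* Quantile-normalization ties receive the average of the reference values
  of the tied ranks, so ties stay ties and the transform is idempotent.
* z-scoring uses the population (1/n) SD; invariant tests depend on it.
* "Sum of eigenvalues" for the low-rank penalty is implemented as the
  nuclear norm (sum of singular values), the standard convex surrogate.
* The NET penalty is implemented literally (no 1/t scaling).
* At n_d = t no test cohort exists; full-subset models are used only for
  vertical consistency and stability.
* Parallel cells derive per-cell seeds by seed-sequence spawning, so
  results do not depend on worker count (the reference drivers run
  serially).
* Degenerate inputs fail loudly: single-class cohorts, empty gene
  intersections, constant profiles (correlation undefined), rank-deficient
  adjustment designs and non-±1 labels all raise.

## Scale of the shipped experiments

The analysis drivers and tests run the full chain at p = 300–500 genes,
five cohorts of 60 subjects and B = 20 bootstraps — sizes chosen so every
experiment reruns from scratch in minutes on one core while preserving the
qualitative regime (weak shared signal, dominant batch offsets, matched
1:1 cohorts).  Known consequences of the scaled-down setting: consistency
and stability values are higher than they would be at transcriptome scale
(fewer noise dimensions), and CV selection is noisier (fewer subjects per
fold).  Directional comparisons (NET vs SVM orderings, variance trends
across n_d) are the meaningful outputs at this scale, not the absolute
values.

## Known limitations

* The EB adjuster implements the parametric variant only.
* Matching is without replacement; no optimal (Hungarian) matching.
* No AUC or significance testing between algorithms; accuracy is the
  proportion correct on 1:1-matched cohorts.
* The regression extension of the MTL objectives is out of scope.
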