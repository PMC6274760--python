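# crosscohort-mtl

Multi-task learning for cross-cohort case-control transcriptomics.

## The problem

Gene-expression case-control studies of psychiatric illness (the motivating
use case is schizophrenia post-mortem brain expression) are individually
small, and cohort-specific technical variation — platform, brain region,
tissue handling — typically outweighs the diagnostic signal.  A classifier
trained on pooled cohorts tends to chase cohort effects; one trained on a
single cohort does not generalize.  This package implements and compares
two integration strategies on a common footing:

* **multi-task learning (MTL)** — each cohort is a classification *task*;
  all tasks are fitted jointly with a cross-task penalty so that the model
  looks for diagnostic patterns that replicate across cohorts;
* **single-task learning (STL)** — lasso logistic regression, linear SVM
  and random forest on the concatenated cohorts.

All MTL formulations minimize the task-averaged logistic loss

L(W, C) = Σᵢ (1/nᵢ) Σⱼ log(1 + exp(−Y.. (X.. · Wᵢ + Cᵢ)))

plus one of five penalties: mean-regularized (**NET**,
λ Σᵢ ‖Wᵢ − W̄‖²), its sparse variant (**SNET**), joint feature selection
(**L21**, λ‖W‖₂,₁), its elastic-net variant (**EN**) and the low-rank
nuclear-norm penalty (**TRACE**, λ‖W‖₊).  The solver is a monotone FISTA
with backtracking; the lasso baseline is the t = 1 case of the same
objective, so losses are exactly comparable.  Around the learners the
package provides the full experimental apparatus: a synthetic multi-cohort
generator with known ground truth, the preprocessing pipeline (probe
collapsing, gene intersection, 1:1 propensity matching, quantile
normalization, empirical-Bayes batch adjustment, z-scoring),
leave-dataset-out evaluation with stratified 5-fold CV, and bootstrap
consistency / stability / success-rate statistics on signed gene profiles.
See `docs/methods.md` for the model details and design choices.

## Worked example

The numbered scripts under `analysis/` rerun the whole study on synthetic
data (five cohorts, 300 genes, 60 subjects each; weak shared signature
β = 0.8 SD on 20 genes under batch offsets of SD 2):

```bash
python analysis/01_simulate.py --seed 0      # writes scratch/data/
python analysis/02_preprocess.py             # writes scratch/processed/
python analysis/03_evaluate.py --seed 0      # writes results/accuracy_*.csv
python analysis/04_robustness.py --seed 0    # writes results/robustness_*.csv
python analysis/05_recovery.py --seed 0      # writes results/recovery.csv
```

`01_simulate` prints, per cohort, the mean case-control shift on signature
genes (0.6–0.9 SD) against the batch-offset SD (≈2 SD) — the signal is
buried in cohort heterogeneity.  `03_evaluate` then shows the
held-out-cohort comparison after preprocessing (output at seed 0):

```
mean held-out accuracy (SE over repetitions):
algorithm  n_d  mean_accuracy  se_over_repetitions
    LR_L1    2       0.820926             0.002690
    LR_L1    3       0.830556             0.003546
    LR_L1    4       0.833333             0.011706
      NET    2       0.821667             0.000321
      NET    3       0.839444             0.000735
      NET    4       0.831111             0.001111
  SVM_LIN    2       0.798333             0.000000
  SVM_LIN    3       0.825000             0.000962
  SVM_LIN    4       0.813333             0.005092

across-test-set spread of accuracies (mean SD per repetition):
algorithm  n_d  mean_across_test_sd
    LR_L1    2             0.059166
    LR_L1    3             0.058477
    LR_L1    4             0.071961
      NET    2             0.034214
      NET    3             0.025322
      NET    4             0.016100
  SVM_LIN    2             0.041140
  SVM_LIN    3             0.032602
  SVM_LIN    4             0.035672
```

Mean accuracies of the three learners sit within a few points of each
other, but their *variability* differs sharply: the jointly regularized
NET has by far the smallest repetition SE, and its across-test-set spread
shrinks steadily as training cohorts are added (0.034 → 0.016) while the
single-task learners' does not — NET's accuracy comes from predicting all
held-out cohorts comparably rather than one of them very well.
`04_robustness` compares the signed gene profiles of NET and the SVM
across 20 stratified bootstraps: consistency grows with n_d for both
algorithms, and NET beats the SVM on horizontal consistency, vertical
consistency and stability with paired success rates of 1.0 across the
board.  `05_recovery` shows why: against the generator's ground truth, the
NET profile correlates with the true shared effect vector at r ≈ 0.87,
versus r ≈ 0.6 for independent per-cohort lasso profiles.

The same machinery is scriptable through a small CLI
(`crosscohort-mtl synth|preprocess|evaluate|robustness|demo|run-all`),
driven by a YAML config and writing a manifest (config hash, seeds,
package version) next to every output.

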