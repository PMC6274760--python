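"""Leave-dataset-out evaluation with stratified cross-validation.

Given cohorts D = {d1..dT}, every training subset d with |d| >= 2 is
enumerated; a model is trained on d (hyperparameters selected by stratified
k-fold CV inside d) and tested on each held-out cohort of D - d separately.
Generalizability is the accuracy on cohorts never seen during training.

The CV protocol differs between learner families, mirroring how each is
deployed: multi-task learners train per-cohort on the training folds and
score each held-out cohort's fold by averaging task scores, then average
accuracy across cohorts; single-task learners pool the training folds and
score the pooled held-out folds.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import baselines, solvers
from .data import CohortDataset, MultiTaskData

logger = logging.getLogger("crosscohort_mtl")

MTL_ALGORITHMS = ("NET", "SNET", "L21", "EN", "TRACE")
STL_ALGORITHMS = ("LR_L1", "SVM_LIN", "RF")


# -- subset plan -----------------------------------------------------------

@dataclass
class SubsetPlan:
    """All training subsets of size >= 2 with their held-out test cohorts."""

    cohort_ids: list[str]
    subsets: list[tuple[tuple[int, ...], tuple[int, ...]]]   # (train, test) indices

    def by_size(self, n_d: int) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
        return [(tr, te) for tr, te in self.subsets if len(tr) == n_d]


def subset_plan(cohort_ids: list[str], min_size: int = 2) -> SubsetPlan:
    T = len(cohort_ids)
    subsets = []
    for size in range(min_size, T + 1):
        for train in itertools.combinations(range(T), size):
            test = tuple(i for i in range(T) if i not in train)
            subsets.append((train, test))
    return SubsetPlan(list(cohort_ids), subsets)


# -- stratified folds ------------------------------------------------------

def make_folds(data: MultiTaskData, k: int, seed: int) -> dict[str, np.ndarray]:
    """Fold index per sample, stratified by cohort and diagnosis.

    Each (cohort x class) cell is shuffled and dealt round-robin over the k
    folds, so cell counts differ by at most one across folds.  Deterministic
    given ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for i, cohort in enumerate(data.cohorts):
        n = cohort.n_samples
        if n == 0:
            raise ValueError(f"cohort {cohort.cohort_id!r} is empty")
        folds = np.full(n, -1, dtype=int)
        y = cohort.labels()
        for cls in (-1.0, 1.0):
            idx = np.flatnonzero(y == cls)
            if 0 < len(idx) < k:
                warnings.warn(
                    f"cohort {cohort.cohort_id!r}: class cell of size "
                    f"{len(idx)} < k={k}; some folds will lack this class"
                )
            rng.shuffle(idx)
            folds[idx] = np.arange(len(idx)) % k
        out[cohort.cohort_id] = folds
    return out


def _subset_rows(cohort: CohortDataset, mask: np.ndarray) -> CohortDataset:
    ids = [s for s, m in zip(cohort.meta["sample_id"], mask) if m]
    return cohort.subset_samples(ids)


# -- scoring helpers -------------------------------------------------------

def _accuracy(labels_true: np.ndarray, labels_pred: np.ndarray) -> float:
    return float(np.mean(labels_true == labels_pred))


def _fit_mtl(train: MultiTaskData, algorithm: str, params: dict,
             opts: solvers.SolverOptions | None):
    return solvers.fit(train, algorithm, lam=params["lam"],
                       alpha=params.get("alpha"), opts=opts)


def _fit_stl(train: MultiTaskData, algorithm: str, params: dict,
             seed: int | None, opts: solvers.SolverOptions | None):
    X, Y = train.pooled()
    return baselines.fit_stl(X, Y, algorithm, params, seed=seed, opts=opts)


def fit_algorithm(train: MultiTaskData, algorithm: str, params: dict,
                  seed: int | None = None,
                  opts: solvers.SolverOptions | None = None):
    """Dispatch to the multi-task solver or a pooled single-task baseline."""
    if algorithm in MTL_ALGORITHMS:
        return _fit_mtl(train, algorithm, params, opts)
    if algorithm in STL_ALGORITHMS:
        return _fit_stl(train, algorithm, params, seed, opts)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def score_cohort(model, algorithm: str, cohort: CohortDataset) -> float:
    """Accuracy of a fitted model on one cohort (task scores averaged for MTL)."""
    X = cohort.expr.to_numpy().T
    y = cohort.labels()
    if algorithm in MTL_ALGORITHMS:
        _, pred = solvers.predict(model, X)
    else:
        pred = baselines.predict_stl(model, X)
    return _accuracy(y, pred)


def _grid_points(grid: dict) -> list[dict]:
    keys = sorted(grid)
    return [dict(zip(keys, vals))
            for vals in itertools.product(*(np.asarray(grid[k]).tolist()
                                            for k in keys))]


def _tie_break_key(algorithm: str, params: dict) -> tuple:
    # prefer stronger regularization on ties: larger lam (MTL/LR), smaller C
    if "C" in params:
        return (-params["C"],)
    return (params.get("lam", 0.0), params.get("alpha", 0.0))


def cross_validate(data: MultiTaskData, algorithm: str, grid: dict, k: int,
                   seed: int, opts: solvers.SolverOptions | None = None) -> dict:
    """Select hyperparameters by stratified k-fold CV; returns the best point.

    The CV score of a grid point is the mean over folds of the fold
    accuracy, where a fold's accuracy is the across-cohort mean of held-out
    cohort accuracies (multi-task) or the pooled held-out accuracy
    (single-task).  Ties prefer stronger regularization.
    """
    points = _grid_points(grid)
    if not points:
        raise ValueError("empty hyperparameter grid")
    if len(points) == 1:
        return points[0]
    folds = make_folds(data, k, seed)
    fold_masks = []
    for fold in range(k):
        train_cohorts, test_cohorts = [], []
        for c in data.cohorts:
            mask = folds[c.cohort_id] != fold
            train_cohorts.append(_subset_rows(c, mask))
            test_cohorts.append(_subset_rows(c, ~mask))
        fold_masks.append((train_cohorts, test_cohorts))

    best, best_score = None, -np.inf
    for params in points:
        fold_scores = []
        for train_cohorts, test_cohorts in fold_masks:
            train = MultiTaskData(train_cohorts, data.gene_ids)
            if algorithm in MTL_ALGORITHMS:
                model = _fit_mtl(train, algorithm, params, opts)
                accs = []
                for tc in test_cohorts:
                    if tc.n_samples == 0:
                        continue
                    if len(set(tc.meta["diagnosis"])) < 2:
                        warnings.warn(
                            f"CV fold: cohort {tc.cohort_id!r} has one class "
                            f"in its test fold; skipped in the average"
                        )
                        continue
                    accs.append(score_cohort(model, algorithm, tc))
                fold_scores.append(float(np.mean(accs)) if accs else np.nan)
            else:
                model = _fit_stl(train, algorithm, params, seed, opts)
                X = np.vstack([tc.expr.to_numpy().T for tc in test_cohorts
                               if tc.n_samples])
                y = np.concatenate([tc.labels() for tc in test_cohorts
                                    if tc.n_samples])
                fold_scores.append(_accuracy(y, baselines.predict_stl(model, X)))
        score = float(np.nanmean(fold_scores))
        if score > best_score or (
            score == best_score
            and _tie_break_key(algorithm, params) > _tie_break_key(algorithm, best)
        ):
            best, best_score = params, score
    return best


# -- leave-dataset-out -----------------------------------------------------

def default_grid(algorithm: str) -> dict:
    if algorithm in MTL_ALGORITHMS:
        return {k: v for k, v in solvers.GRIDS[algorithm].items()}
    return dict(baselines.BASELINE_GRIDS[algorithm])


def leave_dataset_out(data: MultiTaskData, algorithms, n_d: int,
                      repetitions: int = 10, seed: int = 0,
                      grids: dict | None = None, k: int = 5,
                      opts: solvers.SolverOptions | None = None) -> pd.DataFrame:
    """Train on every subset of ``n_d`` cohorts, test on each held-out cohort.

    Each repetition re-randomizes the CV folds used for hyperparameter
    selection (fresh seed per repetition), refits on the whole subset at the
    selected point, and appends one row per (algorithm, subset, test cohort,
    repetition).  ``algorithms`` may mix names with custom objects exposing
    ``name``, ``fit(train, seed)`` and ``score(model, cohort)`` (used as-is,
    no CV) — handy for oracle sanity checks.
    """
    if n_d >= data.t:
        raise ValueError("n_d must leave at least one held-out cohort")
    plan = subset_plan(data.cohort_ids)
    rows = []
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(repetitions)
    for rep in range(repetitions):
        for subset_idx, (train_idx, test_idx) in enumerate(plan.by_size(n_d)):
            train = data.subset(list(train_idx))
            subset_name = "+".join(data.cohort_ids[i] for i in train_idx)
            fold_seed = int(
                np.random.SeedSequence([int(rep_seeds[rep]), subset_idx])
                .generate_state(1)[0] % (2**31)
            )
            for alg in algorithms:
                if isinstance(alg, str):
                    grid = (grids or {}).get(alg, default_grid(alg))
                    points = _grid_points(grid) if grid else [{}]
                    if alg == "RF" or len(points) == 1:
                        params = points[0]
                    else:
                        params = cross_validate(train, alg, grid, k, fold_seed,
                                                opts)
                    model = fit_algorithm(train, alg, params, seed=fold_seed,
                                          opts=opts)
                    for ti in test_idx:
                        rows.append({
                            "algorithm": alg, "n_d": n_d,
                            "train_subset": subset_name,
                            "test_cohort": data.cohort_ids[ti],
                            "repetition": rep,
                            "accuracy": score_cohort(model, alg,
                                                     data.cohorts[ti]),
                            "lam": params.get("lam", np.nan),
                            "alpha": params.get("alpha", np.nan),
                            "C": params.get("C", np.nan),
                        })
                else:   # custom algorithm object (e.g. an oracle)
                    model = alg.fit(train, fold_seed)
                    for ti in test_idx:
                        rows.append({
                            "algorithm": alg.name, "n_d": n_d,
                            "train_subset": subset_name,
                            "test_cohort": data.cohort_ids[ti],
                            "repetition": rep,
                            "accuracy": alg.score(model, data.cohorts[ti]),
                            "lam": np.nan, "alpha": np.nan, "C": np.nan,
                        })
    table = pd.DataFrame(rows)
    bad = table[(table["accuracy"] < 0) | (table["accuracy"] > 1)]
    assert bad.empty, "accuracy outside [0, 1]"
    return table


def summarize(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-algorithm accuracy summaries of a leave-dataset-out table.

    Returns
    -------
    dict with:
      ``mean``          mean accuracy per (algorithm, n_d), first averaging
                        within repetitions, plus the SE over repetition means.
      ``test_set_se``   per (algorithm, n_d, repetition) the across-test-set
                        standard error of subset-level accuracies.
    """
    if table.empty:
        raise ValueError("empty accuracy table")
    rep_means = (
        table.groupby(["algorithm", "n_d", "repetition"])["accuracy"]
        .mean().rename("rep_mean").reset_index()
    )

    def _se(x):
        x = np.asarray(x, dtype=float)
        if len(x) < 2:
            return 0.0
        return float(np.std(x, ddof=1) / np.sqrt(len(x)))

    mean = (
        rep_means.groupby(["algorithm", "n_d"])["rep_mean"]
        .agg(mean_accuracy="mean", se_over_repetitions=_se,
             n_repetitions="count")
        .reset_index()
    )
    test_se = (
        table.groupby(["algorithm", "n_d", "repetition"])["accuracy"]
        .agg(across_test_se=_se, across_test_sd=lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0)
        .reset_index()
    )
    return {"mean": mean, "test_set_se": test_se}
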