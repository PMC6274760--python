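"""Bootstrap robustness of transcriptomic profiles.

A *profile* is the signed per-gene coefficient vector of a fitted model;
for a multi-task model it is the across-task mean of the weight columns.
Profiles are compared with the Pearson correlation over all genes, and
three summary statistics are built from stratified bootstrap replicates:

``horizontal consistency``  mean pairwise profile correlation among models
    trained on different cohort subsets of the same size (one value per
    bootstrap replicate) — robustness to *which* cohorts were used.
``vertical consistency``    mean correlation between the all-cohorts model
    and each model trained on fewer cohorts (per replicate) — sensitivity
    to the number of training cohorts.
``stability``               mean pairwise correlation across bootstrap
    replicates of the same training subset — robustness to sampling
    variability.
``success rate``            fraction of paired comparisons in which one
    algorithm's metric strictly exceeds another's (ties count as failures).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import baselines, evaluate, solvers
from .baselines import STLModel
from .data import MultiTaskData
from .solvers import MTLModel

logger = logging.getLogger("crosscohort_mtl")


# -- profiles and similarity ----------------------------------------------

def profile(model, allow_unsigned: bool = False) -> np.ndarray:
    """Signed per-gene coefficient vector of a fitted model.

    Multi-task models yield the row-wise mean of W; single-task linear
    models their weight vector.  Random-forest importances are unsigned and
    not comparable to signed profiles, so they are rejected unless
    ``allow_unsigned=True``.
    """
    if isinstance(model, MTLModel):
        return model.W.mean(axis=1)
    if isinstance(model, STLModel):
        if model.algorithm == "RF" and not allow_unsigned:
            raise ValueError(
                "random-forest importances are unsigned; pass "
                "allow_unsigned=True to use them anyway"
            )
        return np.asarray(model.profile, dtype=float)
    raise TypeError(f"cannot extract a profile from {type(model).__name__}")


def similarity(p1: np.ndarray, p2: np.ndarray) -> float:
    """Pearson correlation between two profiles (error on constant input)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape or p1.ndim != 1 or len(p1) < 2:
        raise ValueError("profiles must be 1-D, equal length >= 2")
    if np.std(p1) == 0.0 or np.std(p2) == 0.0:
        raise ValueError("correlation undefined for a constant profile")
    return float(np.corrcoef(p1, p2)[0, 1])


def _mean_pairwise(profiles: list[np.ndarray]) -> float:
    pairs = list(itertools.combinations(range(len(profiles)), 2))
    return float(np.mean([similarity(profiles[i], profiles[j])
                          for i, j in pairs]))


def horizontal_consistency(profiles: list[np.ndarray]) -> float:
    """Mean pairwise similarity among same-size-subset profiles."""
    if len(profiles) < 2:
        raise ValueError("horizontal consistency needs >= 2 subset profiles")
    return _mean_pairwise(profiles)


def vertical_consistency(full_profile: np.ndarray,
                         profiles: list[np.ndarray]) -> float:
    """Mean similarity between the all-cohorts profile and smaller-subset ones."""
    if full_profile is None:
        raise ValueError("missing full-data (all-cohorts) profile")
    if not profiles:
        raise ValueError("no lower-n_d profiles given")
    return float(np.mean([similarity(full_profile, q) for q in profiles]))


def stability(profiles: list[np.ndarray]) -> float:
    """Mean pairwise similarity across bootstrap replicates of one subset."""
    if len(profiles) < 2:
        raise ValueError("stability needs >= 2 bootstrap profiles")
    return _mean_pairwise(profiles)


def success_rate(values_a, values_b) -> float:
    """Fraction of paired comparisons where A strictly beats B (ties fail)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired metric vectors must have equal length")
    return float(np.mean(a > b))


# -- stratified bootstrap --------------------------------------------------

def bootstrap_samples(data: MultiTaskData, B: int, seed: int) -> list[MultiTaskData]:
    """B stratified bootstrap replicates of the subjects.

    Within every (cohort x diagnosis) cell, subjects are resampled with
    replacement to the original cell size, so class balance and cohort
    sizes are preserved exactly.  Deterministic given ``seed``.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    replicates = []
    for _ in range(B):
        cohorts = []
        for c in data.cohorts:
            ids = np.asarray(c.meta["sample_id"])
            y = c.labels()
            chosen: list[str] = []
            for cls in (1.0, -1.0):
                cell = ids[y == cls]
                if len(cell) == 0:
                    raise ValueError(
                        f"cohort {c.cohort_id!r}: empty "
                        f"{'case' if cls > 0 else 'control'} cell"
                    )
                chosen.extend(rng.choice(cell, size=len(cell), replace=True))
            cohorts.append(c.subset_samples(chosen))
        replicates.append(MultiTaskData(cohorts, data.gene_ids))
    return replicates


# -- full robustness experiment -------------------------------------------

@dataclass
class RobustnessReport:
    """Consistency/stability values plus helpers for paired success rates."""

    consistency: pd.DataFrame   # algorithm, kind, n_d, bootstrap, value
    stability: pd.DataFrame     # algorithm, train_subset, n_d, value
    hyperparams: dict = field(default_factory=dict)

    def validate(self) -> None:
        v = self.consistency["value"]
        assert ((v >= -1 - 1e-12) & (v <= 1 + 1e-12)).all(), "consistency outside [-1, 1]"
        v = self.stability["value"]
        assert ((v >= -1 - 1e-12) & (v <= 1 + 1e-12)).all(), "stability outside [-1, 1]"

    def consistency_success_rate(self, alg_a: str, alg_b: str, kind: str,
                                 n_d: int) -> float:
        """Success rate of A over B, paired by bootstrap replicate."""
        sub = self.consistency[(self.consistency["kind"] == kind)
                               & (self.consistency["n_d"] == n_d)]
        a = sub[sub["algorithm"] == alg_a].sort_values("bootstrap")["value"]
        b = sub[sub["algorithm"] == alg_b].sort_values("bootstrap")["value"]
        return success_rate(a.to_numpy(), b.to_numpy())

    def stability_success_rate(self, alg_a: str, alg_b: str,
                               n_d: int | None = None) -> float:
        """Success rate of A over B, paired by training subset."""
        sub = self.stability
        if n_d is not None:
            sub = sub[sub["n_d"] == n_d]
        a = sub[sub["algorithm"] == alg_a].sort_values("train_subset")["value"]
        b = sub[sub["algorithm"] == alg_b].sort_values("train_subset")["value"]
        return success_rate(a.to_numpy(), b.to_numpy())

    def summary(self) -> pd.DataFrame:
        """Mean consistency per (algorithm, kind, n_d) and mean stability."""
        cons = (self.consistency.groupby(["algorithm", "kind", "n_d"])["value"]
                .mean().rename("mean").reset_index())
        stab = (self.stability.groupby(["algorithm", "n_d"])["value"]
                .mean().rename("mean").reset_index())
        stab["kind"] = "stability"
        return pd.concat([cons, stab[["algorithm", "kind", "n_d", "mean"]]],
                         ignore_index=True)

    def to_long(self) -> pd.DataFrame:
        """Tidy long table for :func:`crosscohort_mtl.io.write_report`."""
        cons = self.consistency.rename(columns={"bootstrap": "replicate"})
        cons = cons.assign(
            subset="all@n_d=" + cons["n_d"].astype(str),
            metric=cons["kind"] + "_consistency",
        )[["algorithm", "subset", "replicate", "metric", "value"]]
        stab = self.stability.assign(
            subset=self.stability["train_subset"], replicate=-1,
            metric="stability",
        )[["algorithm", "subset", "replicate", "metric", "value"]]
        return pd.concat([cons, stab], ignore_index=True)


def run_robustness(data: MultiTaskData, algorithms: list[str], B: int = 100,
                   seed: int = 0, subset_sizes: tuple[int, ...] = (2, 3, 4, 5),
                   hyperparams: dict | None = None, cv_k: int = 5,
                   opts: solvers.SolverOptions | None = None) -> RobustnessReport:
    """Fit every (algorithm, training subset, bootstrap replicate) model and
    summarize profile consistency and stability.

    Hyperparameters are selected once per (algorithm, subset) by CV on the
    original data and reused across bootstrap replicates; pass
    ``hyperparams={alg: {...}}`` to pin them instead.
    """
    plan = evaluate.subset_plan(data.cohort_ids)
    sizes = sorted(set(subset_sizes))
    full_size = data.t
    replicates = bootstrap_samples(data, B, seed)
    ss = np.random.SeedSequence(seed)
    rf_seeds = ss.generate_state(B)

    # hyperparameter selection on the original (non-resampled) data
    chosen: dict[tuple[str, tuple[int, ...]], dict] = {}
    for alg in algorithms:
        for size in sizes:
            for train_idx, _ in plan.by_size(size):
                if hyperparams and alg in hyperparams:
                    chosen[(alg, train_idx)] = dict(hyperparams[alg])
                    continue
                grid = evaluate.default_grid(alg)
                points = evaluate._grid_points(grid) if grid else [{}]
                if alg == "RF" or len(points) == 1:
                    chosen[(alg, train_idx)] = points[0]
                else:
                    cv_seed = int(np.random.SeedSequence(
                        [seed, size, hash(train_idx) % (2**31)]
                    ).generate_state(1)[0] % (2**31))
                    chosen[(alg, train_idx)] = evaluate.cross_validate(
                        data.subset(list(train_idx)), alg, grid, cv_k,
                        cv_seed, opts)

    # profiles per (algorithm, subset, replicate)
    profiles: dict[tuple[str, tuple[int, ...], int], np.ndarray] = {}
    for b, rep in enumerate(replicates):
        for alg in algorithms:
            for size in sizes:
                for train_idx, _ in plan.by_size(size):
                    model = evaluate.fit_algorithm(
                        rep.subset(list(train_idx)), alg,
                        chosen[(alg, train_idx)],
                        seed=int(rf_seeds[b] % (2**31)), opts=opts)
                    profiles[(alg, train_idx, b)] = profile(
                        model, allow_unsigned=(alg == "RF"))

    cons_rows, stab_rows = [], []
    for alg in algorithms:
        for b in range(B):
            full = None
            if full_size in sizes:
                (full_idx, _), = plan.by_size(full_size)
                full = profiles[(alg, full_idx, b)]
            for size in sizes:
                subs = [train_idx for train_idx, _ in plan.by_size(size)]
                profs = [profiles[(alg, s, b)] for s in subs]
                if len(profs) >= 2:
                    cons_rows.append({"algorithm": alg, "kind": "horizontal",
                                      "n_d": size, "bootstrap": b,
                                      "value": horizontal_consistency(profs)})
                if full is not None and size < full_size:
                    cons_rows.append({"algorithm": alg, "kind": "vertical",
                                      "n_d": size, "bootstrap": b,
                                      "value": vertical_consistency(full, profs)})
        for size in sizes:
            for train_idx, _ in plan.by_size(size):
                profs = [profiles[(alg, train_idx, b)] for b in range(B)]
                stab_rows.append({
                    "algorithm": alg,
                    "train_subset": "+".join(data.cohort_ids[i]
                                             for i in train_idx),
                    "n_d": size, "value": stability(profs),
                })

    cons_cols = ["algorithm", "kind", "n_d", "bootstrap", "value"]
    stab_cols = ["algorithm", "train_subset", "n_d", "value"]
    report = RobustnessReport(pd.DataFrame(cons_rows, columns=cons_cols),
                              pd.DataFrame(stab_rows, columns=stab_cols),
                              {f"{a}@{tr}": p for (a, tr), p in chosen.items()})
    report.validate()
    return report
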