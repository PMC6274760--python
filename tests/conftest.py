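"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from crosscohort_mtl.data import CohortDataset, MultiTaskData


def make_tasks(t=2, p=3, n=20, seed=0, noise=0.3):
    """Small random two-class tasks with a linear signal (labels +/-1)."""
    rng = np.random.default_rng(seed)
    tasks = []
    for _ in range(t):
        X = rng.normal(size=(n, p))
        w = rng.normal(size=p)
        Y = np.where(X @ w + noise * rng.normal(size=n) > 0, 1.0, -1.0)
        if len(np.unique(Y)) < 2:   # force both classes
            Y[0] = -Y[0]
        tasks.append((X, Y))
    return tasks


def pool(tasks):
    return [(np.vstack([X for X, _ in tasks]),
             np.concatenate([Y for _, Y in tasks]))]


def make_cohort(cohort_id="c1", p=5, n=8, seed=0, balanced=True) -> CohortDataset:
    rng = np.random.default_rng(seed)
    genes = [f"G{i+1:03d}" for i in range(p)]
    samples = [f"{cohort_id}_s{j+1}" for j in range(n)]
    expr = pd.DataFrame(rng.normal(size=(p, n)), index=genes, columns=samples)
    n_case = n // 2 if balanced else max(1, n // 3)
    meta = pd.DataFrame({
        "sample_id": samples,
        "diagnosis": ["case"] * n_case + ["control"] * (n - n_case),
        "sex": rng.choice(["m", "f"], size=n),
        "age": rng.uniform(30, 80, size=n).round(1),
        "pmi": rng.uniform(5, 40, size=n).round(1),
        "ph": rng.normal(6.4, 0.2, size=n).round(2),
    })
    return CohortDataset(cohort_id, expr, meta)


def make_multitask(t=3, p=10, n=12, seed=0) -> MultiTaskData:
    return MultiTaskData([make_cohort(f"c{i+1}", p, n, seed + i)
                          for i in range(t)])


def oracle_minimize(obj, n_vars, restarts=8, x0=None):
    """Generic derivative-free convex minimizer: iterated Nelder-Mead.

    Restarting the simplex from the previous optimum — alternating plain
    restarts with small random perturbations to re-expand a collapsed
    simplex — drives the objective to near machine precision on small
    smooth or piecewise-smooth convex problems.
    """
    rng = np.random.default_rng(0)
    z = np.zeros(n_vars) if x0 is None else np.asarray(x0, dtype=float)
    best = None
    for r in range(restarts):
        res = minimize(obj, z, method="Nelder-Mead",
                       options=dict(maxiter=50000, maxfev=50000,
                                    fatol=1e-14, xatol=1e-12))
        if best is None or res.fun < best.fun:
            best = res
        # odd rounds: jiggle the incumbent to escape simplex collapse
        scale = 10.0 ** -(2 + r % 3)
        z = best.x + (rng.normal(size=n_vars) * scale if r % 2 else 0.0)
    return best


@pytest.fixture
def tiny_tasks():
    return make_tasks(t=2, p=3, n=20, seed=42)


@pytest.fixture
def small_multitask():
    return make_multitask()
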