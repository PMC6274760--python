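"""Regularized multi-task logistic regression via accelerated proximal gradient.

All formulations share the task-averaged logistic loss

    L(W, C) = sum_i (1/n_i) sum_j log(1 + exp(-Y_ij (X_ij . W_i + C_i)))

over t tasks (cohorts) with labels in {-1, +1}, and differ only in the
cross-task penalty:

``NET``    mean-regularized MTL: lambda * sum_i ||W_i - mean_j W_j||_2^2,
           pulling every task's weight vector toward the across-task mean
           (both effect sizes and signs are harmonized).
``SNET``   sparse NET: lambda * (alpha * net-term + (1-alpha) * ||W||_1).
``L21``    joint feature selection: lambda * sum_g ||W^g||_2 over gene rows,
           selecting or rejecting a gene for all tasks at once.
``EN``     L21 elastic net: lambda * ((1-alpha) * ||W||_{2,1} + alpha * ||W||_F^2).
``TRACE``  low-rank MTL: lambda * nuclear norm of W (sum of singular values).
``LR_L1``  single-task lasso logistic regression, the t=1 degenerate case.

The optimizer is a monotone FISTA with backtracking line search: smooth
terms (loss, NET deviation, EN Frobenius term) enter the gradient, the
nonsmooth terms through their proximal operators.  Intercepts are never
penalized.  Weights produced by soft-thresholding are exact zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

FORMULATIONS = ("NET", "SNET", "L21", "EN", "TRACE", "LR_L1")

#: default hyperparameter grids per formulation (lambda as powers of 10)
GRIDS: dict[str, dict[str, np.ndarray]] = {
    "NET": {"lam": 10.0 ** np.arange(-6, 2 + 1, 1.0)},
    "SNET": {"lam": 10.0 ** np.arange(-6, 2 + 1, 1.0),
             "alpha": np.round(np.arange(0.0, 1.01, 0.1), 10)},
    "L21": {"lam": 10.0 ** np.round(np.arange(-6, 0 + 1e-9, 0.1), 10)},
    "EN": {"lam": 10.0 ** np.round(np.arange(-6, 0 + 1e-9, 0.1), 10),
           "alpha": np.round(np.arange(0.0, 1.01, 0.1), 10)},
    "TRACE": {"lam": 10.0 ** np.round(np.arange(-6, 1 + 1e-9, 0.1), 10)},
    "LR_L1": {"lam": 10.0 ** np.round(np.arange(-10, 1 + 1e-9, 0.5), 10)},
}


@dataclass
class SolverOptions:
    tol: float = 1e-6          # relative objective-change stopping rule
    max_iter: int = 2000
    step_init: float = 1.0     # initial line-search step
    step_shrink: float = 0.5
    step_grow: float = 1.2     # optimistic growth between iterations


@dataclass
class MTLModel:
    """A fitted multi-task (or single-task) logistic model."""

    W: np.ndarray                  # p x t weight matrix
    C: np.ndarray                  # length-t intercepts
    formulation: str
    lam: float
    alpha: float | None = None
    converged: bool = False
    n_iter: int = 0
    objective_trace: list[float] = field(default_factory=list)
    gene_ids: list[str] | None = None

    @property
    def t(self) -> int:
        return self.W.shape[1]

    @property
    def p(self) -> int:
        return self.W.shape[0]


def _as_tasks(data) -> list[tuple[np.ndarray, np.ndarray]]:
    tasks = data.tasks() if hasattr(data, "tasks") else list(data)
    for X, Y in tasks:
        bad = set(np.unique(Y)) - {-1.0, 1.0}
        if bad:
            raise ValueError(f"labels must be -1/+1, found {sorted(bad)}")
    return tasks


def logistic_loss(W: np.ndarray, C: np.ndarray, data):
    """Task-averaged logistic loss and its gradients.

    Returns ``(value, grad_W, grad_C)``.  Numerically stable for extreme
    margins through ``logaddexp``/``expit``.
    """
    tasks = _as_tasks(data)
    W = np.asarray(W, dtype=float)
    C = np.asarray(C, dtype=float)
    grad_W = np.zeros_like(W)
    grad_C = np.zeros_like(C)
    value = 0.0
    for i, (X, Y) in enumerate(tasks):
        n_i = X.shape[0]
        margin = Y * (X @ W[:, i] + C[i])
        value += float(np.logaddexp(0.0, -margin).sum()) / n_i
        # d/dm log(1+e^{-m}) = -sigmoid(-m)
        r = -expit(-margin) * Y / n_i
        grad_W[:, i] = X.T @ r
        grad_C[i] = r.sum()
    return value, grad_W, grad_C


def penalty_net(W: np.ndarray, lam: float):
    """Mean-regularized penalty lam * sum_i ||W_i - W_bar||^2 and gradient.

    The gradient with respect to column k simplifies to 2 lam (W_k - W_bar)
    because the deviations sum to zero across tasks.
    """
    W = np.asarray(W, dtype=float)
    dev = W - W.mean(axis=1, keepdims=True)
    return lam * float((dev ** 2).sum()), 2.0 * lam * dev


# -- proximal operators ---------------------------------------------------

def _check_tau(tau: float) -> None:
    if tau < 0:
        raise ValueError(f"threshold tau must be >= 0, got {tau}")


def prox_l1(V: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise soft-thresholding: argmin_w tau*||w||_1 + ||w-v||^2/2."""
    _check_tau(tau)
    V = np.asarray(V, dtype=float)
    return np.sign(V) * np.maximum(np.abs(V) - tau, 0.0)


def prox_l21(V: np.ndarray, tau: float) -> np.ndarray:
    """Row-wise group soft-thresholding for the L2,1 norm over gene rows."""
    _check_tau(tau)
    V = np.atleast_2d(np.asarray(V, dtype=float))
    norms = np.linalg.norm(V, axis=1)
    scale = np.zeros_like(norms)
    nz = norms > tau
    scale[nz] = 1.0 - tau / norms[nz]
    return V * scale[:, None]


def prox_trace(V: np.ndarray, tau: float) -> np.ndarray:
    """Singular-value soft-thresholding for the nuclear (trace) norm."""
    _check_tau(tau)
    V = np.atleast_2d(np.asarray(V, dtype=float))
    U, sv, Vt = np.linalg.svd(V, full_matrices=False)
    sv = np.maximum(sv - tau, 0.0)
    return (U * sv) @ Vt


# -- objective assembly ----------------------------------------------------

def _smooth_value_grad(W, C, tasks, formulation, lam, alpha):
    value, gW, gC = logistic_loss(W, C, tasks)
    if formulation == "NET":
        v, g = penalty_net(W, lam)
        value += v
        gW = gW + g
    elif formulation == "SNET":
        v, g = penalty_net(W, lam * alpha)
        value += v
        gW = gW + g
    elif formulation == "EN":
        value += lam * alpha * float((W ** 2).sum())
        gW = gW + 2.0 * lam * alpha * W
    return value, gW, gC


def _nonsmooth_value(W, formulation, lam, alpha) -> float:
    if formulation in ("SNET",):
        return lam * (1.0 - alpha) * float(np.abs(W).sum())
    if formulation == "LR_L1":
        return lam * float(np.abs(W).sum())
    if formulation == "L21":
        return lam * float(np.linalg.norm(W, axis=1).sum())
    if formulation == "EN":
        return lam * (1.0 - alpha) * float(np.linalg.norm(W, axis=1).sum())
    if formulation == "TRACE":
        return lam * float(np.linalg.svd(W, compute_uv=False).sum())
    return 0.0


def _prox(W, step, formulation, lam, alpha) -> np.ndarray:
    if formulation == "SNET":
        return prox_l1(W, step * lam * (1.0 - alpha))
    if formulation == "LR_L1":
        return prox_l1(W, step * lam)
    if formulation == "L21":
        return prox_l21(W, step * lam)
    if formulation == "EN":
        return prox_l21(W, step * lam * (1.0 - alpha))
    if formulation == "TRACE":
        return prox_trace(W, step * lam)
    return W


def objective(W, C, data, formulation, lam, alpha=None) -> float:
    """Full objective value (loss + smooth penalty + nonsmooth penalty)."""
    tasks = _as_tasks(data)
    value, _, _ = _smooth_value_grad(np.asarray(W, float), np.asarray(C, float),
                                     tasks, formulation, lam, alpha)
    return value + _nonsmooth_value(np.asarray(W, float), formulation, lam, alpha)


# -- solver ----------------------------------------------------------------

def fit(data, formulation: str, lam: float, alpha: float | None = None,
        opts: SolverOptions | None = None,
        gene_ids: list[str] | None = None) -> MTLModel:
    """Fit one formulation by monotone FISTA with backtracking.

    The extrapolated candidate is accepted only if it does not increase the
    objective; otherwise momentum is restarted and a plain proximal-gradient
    step is taken, so the objective trace is non-increasing.  Stops when the
    relative objective change drops below ``opts.tol`` or at
    ``opts.max_iter`` (``converged`` flag records which).
    """
    if formulation not in FORMULATIONS:
        raise ValueError(f"unknown formulation {formulation!r}")
    if formulation in ("SNET", "EN"):
        if alpha is None:
            raise ValueError(f"{formulation} requires alpha")
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    opts = opts or SolverOptions()
    tasks = _as_tasks(data)
    if formulation == "LR_L1" and len(tasks) != 1:
        raise ValueError("LR_L1 is single-task; pool the data first")
    p = tasks[0][0].shape[1]
    t = len(tasks)
    if gene_ids is None and hasattr(data, "gene_ids"):
        gene_ids = list(data.gene_ids)

    def F(W, C):
        v, _, _ = _smooth_value_grad(W, C, tasks, formulation, lam, alpha)
        return v + _nonsmooth_value(W, formulation, lam, alpha)

    W = np.zeros((p, t))
    C = np.zeros(t)
    Wy, Cy = W.copy(), C.copy()
    F_x = F(W, C)
    trace = [F_x]
    tk = 1.0
    step = opts.step_init
    converged = False
    it = 0

    def prox_step(Wy, Cy, step):
        """Backtracking proximal-gradient step from (Wy, Cy)."""
        f_y, gW, gC = _smooth_value_grad(Wy, Cy, tasks, formulation, lam, alpha)
        while True:
            Wz = _prox(Wy - step * gW, step, formulation, lam, alpha)
            Cz = Cy - step * gC
            dW, dC = Wz - Wy, Cz - Cy
            sqdist = float((dW ** 2).sum() + (dC ** 2).sum())
            f_z, _, _ = _smooth_value_grad(Wz, Cz, tasks, formulation, lam, alpha)
            if f_z <= f_y + float((gW * dW).sum() + (gC * dC).sum()) + sqdist / (2 * step) + 1e-12:
                return Wz, Cz, step
            step *= opts.step_shrink
            if step < 1e-18:
                raise FloatingPointError("line search collapsed")

    for it in range(1, opts.max_iter + 1):
        step = min(step * opts.step_grow, 1e6)
        Wz, Cz, step = prox_step(Wy, Cy, step)
        F_z = F(Wz, Cz)
        if not math.isfinite(F_z):
            raise FloatingPointError("objective became non-finite")
        if F_z > F_x:
            # extrapolation overshot: restart momentum at the last iterate
            tk = 1.0
            Wz, Cz, step = prox_step(W, C, step)
            F_z = F(Wz, Cz)
        rel = abs(F_x - F_z) / max(1.0, abs(F_z))
        t_next = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * tk * tk))
        Wy = Wz + ((tk - 1.0) / t_next) * (Wz - W)
        Cy = Cz + ((tk - 1.0) / t_next) * (Cz - C)
        W, C, F_x, tk = Wz, Cz, F_z, t_next
        trace.append(F_x)
        if rel < opts.tol:
            converged = True
            break

    return MTLModel(W=W, C=C, formulation=formulation, lam=float(lam),
                    alpha=None if alpha is None else float(alpha),
                    converged=converged, n_iter=it, objective_trace=trace,
                    gene_ids=gene_ids)


def predict(model: MTLModel, X_new: np.ndarray,
            gene_ids: list[str] | None = None):
    """Average-of-task-scores prediction.

    Per task i the score is sigmoid(X W_i + C_i); the final probability of
    the case class is the across-task mean, and samples with probability
    strictly above 0.5 are assigned to the case class (+1), ties to control.
    Returns ``(probability, labels)``.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != model.p:
        raise ValueError(
            f"X_new has {X_new.shape[1]} features, model expects {model.p}"
        )
    if gene_ids is not None and model.gene_ids is not None:
        if list(gene_ids) != list(model.gene_ids):
            raise ValueError("gene order mismatch between model and X_new")
    scores = expit(X_new @ model.W + model.C[None, :])
    prob = scores.mean(axis=1)
    labels = np.where(prob > 0.5, 1.0, -1.0)
    return prob, labels
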