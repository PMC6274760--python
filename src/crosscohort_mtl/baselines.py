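"""Single-task baselines: L1 logistic regression, linear SVM, random forest.

All three operate on the pooled (row-wise concatenated) cohorts and expose
a uniform *profile* contract: a length-p importance vector over genes.  For
the linear models the profile is the signed primal weight vector with the
convention that a positive weight means higher expression in cases; the
forest's profile is the (non-negative) mean impurity decrease, which is why
it is excluded from signed profile-similarity analyses by default.

``LR_L1`` deliberately reuses the in-house proximal-gradient solver with a
single task, so its objective is exactly the multi-task logistic loss plus
an l1 penalty — guaranteeing consistency with the MTL formulations.  SVM
and random forest delegate to scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from . import solvers

ALGORITHMS = ("LR_L1", "SVM_LIN", "RF")

#: default hyperparameter grids (RF is fit once, no grid)
BASELINE_GRIDS: dict[str, dict[str, np.ndarray]] = {
    "LR_L1": {"lam": solvers.GRIDS["LR_L1"]["lam"]},
    "SVM_LIN": {"C": 10.0 ** np.arange(-5, 5 + 1, 1.0)},
    "RF": {},
}

RF_N_TREES = 5000


@dataclass
class STLModel:
    algorithm: str
    profile: np.ndarray                  # length-p coefficients / importances
    intercept: float | None
    hyperparams: dict = field(default_factory=dict)
    estimator: object = None             # underlying fitted model

    @property
    def p(self) -> int:
        return self.profile.shape[0]


def fit_stl(X: np.ndarray, Y: np.ndarray, algorithm: str,
            hyperparams: dict | None = None, seed: int | None = None,
            opts: solvers.SolverOptions | None = None) -> STLModel:
    """Fit one single-task baseline on pooled data.

    ``hyperparams``: ``{"lam": float}`` for LR_L1, ``{"C": float}`` for the
    SVM, optionally ``{"n_trees": int}`` for the forest.  ``seed`` only
    affects the forest (the other fits are deterministic).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if len(np.unique(Y)) < 2:
        raise ValueError("single-class labels: nothing to learn")
    hyperparams = dict(hyperparams or {})
    if algorithm == "LR_L1":
        lam = float(hyperparams.get("lam", 0.0))
        model = solvers.fit([(X, Y)], "LR_L1", lam=lam, opts=opts)
        return STLModel("LR_L1", model.W[:, 0].copy(), float(model.C[0]),
                        {"lam": lam}, model)
    if algorithm == "SVM_LIN":
        C = float(hyperparams.get("C", 1.0))
        svm = SVC(kernel="linear", C=C)
        svm.fit(X, Y)
        # classes_ is sorted [-1, +1], so decision_function > 0 <=> case:
        # positive weights mean higher expression in cases, matching MTL.
        return STLModel("SVM_LIN", svm.coef_.ravel().copy(),
                        float(svm.intercept_[0]), {"C": C}, svm)
    if algorithm == "RF":
        n_trees = int(hyperparams.get("n_trees", RF_N_TREES))
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    n_jobs=1)
        rf.fit(X, Y)
        return STLModel("RF", rf.feature_importances_.copy(), None,
                        {"n_trees": n_trees, "seed": seed}, rf)
    raise ValueError(f"unknown baseline algorithm {algorithm!r}")


def predict_stl(model: STLModel, X_new: np.ndarray) -> np.ndarray:
    """Class labels in {-1, +1}; ties go to control (-1), as for MTL."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != model.p:
        raise ValueError(
            f"X_new has {X_new.shape[1]} features, model expects {model.p}"
        )
    if model.algorithm == "LR_L1":
        _, labels = solvers.predict(model.estimator, X_new)
        return labels
    if model.algorithm == "SVM_LIN":
        margin = X_new @ model.profile + model.intercept
        return np.where(margin > 0, 1.0, -1.0)
    if model.algorithm == "RF":
        return model.estimator.predict(X_new).astype(float)
    raise ValueError(f"unknown baseline algorithm {model.algorithm!r}")
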