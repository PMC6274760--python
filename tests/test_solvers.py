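"""Unit tests for the multi-task solvers: loss, penalties, prox, FISTA."""

import math

import numpy as np
import pytest

from crosscohort_mtl import solvers
from crosscohort_mtl.solvers import (
    GRIDS,
    SolverOptions,
    fit,
    logistic_loss,
    penalty_net,
    predict,
    prox_l1,
    prox_l21,
    prox_trace,
)

from conftest import make_tasks, oracle_minimize, pool

TIGHT = SolverOptions(tol=1e-10, max_iter=20000)


class TestLogisticLoss:
    def test_zero_weights_give_t_log2(self, tiny_tasks):
        """At W=0, C=0 every subject contributes log 2, averaged per task."""
        W = np.zeros((3, 2))
        C = np.zeros(2)
        value, _, _ = logistic_loss(W, C, tiny_tasks)
        assert value == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_single_subject_margin(self):
        """One subject with margin z contributes log(1 + e^-z)."""
        X = np.array([[2.0, -1.0]])
        Y = np.array([1.0])
        W = np.array([[0.5], [1.0]])
        C = np.array([0.25])
        z = 2.0 * 0.5 - 1.0 * 1.0 + 0.25
        value, _, _ = logistic_loss(W, C, [(X, Y)])
        assert value == pytest.approx(math.log1p(math.exp(-z)), rel=1e-12)

    def test_extreme_margins_finite(self):
        X = np.array([[1000.0], [-1000.0]])
        Y = np.array([1.0, 1.0])
        value, gW, gC = logistic_loss(np.array([[1.0]]), np.array([0.0]), [(X, Y)])
        assert np.isfinite(value) and np.isfinite(gW).all() and np.isfinite(gC).all()
        assert value == pytest.approx(500.0, rel=1e-6)   # half of |margin| 1000

    def test_rejects_non_pm1_labels(self):
        X = np.ones((2, 1))
        with pytest.raises(ValueError, match="-1/\\+1"):
            logistic_loss(np.zeros((1, 1)), np.zeros(1), [(X, np.array([0.0, 1.0]))])

    def test_gradient_matches_finite_differences(self, tiny_tasks):
        rng = np.random.default_rng(3)
        W = rng.normal(size=(3, 2)) * 0.5
        C = rng.normal(size=2) * 0.1
        _, gW, gC = logistic_loss(W, C, tiny_tasks)
        eps = 1e-6
        for arr, grad in ((W, gW), (C, gC)):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                up, _, _ = logistic_loss(W, C, tiny_tasks)
                arr[idx] = orig - eps
                down, _, _ = logistic_loss(W, C, tiny_tasks)
                arr[idx] = orig
                fd = (up - down) / (2 * eps)
                assert grad[idx] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestPenaltyNet:
    def test_identical_columns_vanish(self):
        W = np.tile(np.arange(4.0)[:, None], (1, 3))
        value, grad = penalty_net(W, 1.3)
        assert value == 0.0
        assert np.all(grad == 0.0)

    def test_single_task_is_zero(self):
        value, _ = penalty_net(np.arange(5.0)[:, None], 2.0)
        assert value == 0.0

    def test_matches_bruteforce_and_finite_differences(self):
        """Re-derive the penalty by an explicit loop and check the 2*lam*(W-Wbar)
        gradient simplification against central differences."""
        rng = np.random.default_rng(7)
        W = rng.normal(size=(3, 4))
        lam = 0.7
        wbar = W.mean(axis=1)
        brute = lam * sum(np.sum((W[:, i] - wbar) ** 2) for i in range(4))
        value, grad = penalty_net(W, lam)
        assert value == pytest.approx(brute, rel=1e-12)
        eps = 1e-6
        it = np.nditer(W, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = W[idx]
            W[idx] = orig + eps
            up, _ = penalty_net(W, lam)
            W[idx] = orig - eps
            down, _ = penalty_net(W, lam)
            W[idx] = orig
            assert grad[idx] == pytest.approx((up - down) / (2 * eps),
                                              rel=1e-6, abs=1e-9)


class TestProximalOperators:
    @pytest.mark.parametrize("prox", [prox_l1, prox_l21, prox_trace])
    def test_tau_zero_is_identity(self, prox):
        V = np.random.default_rng(0).normal(size=(4, 3))
        assert np.allclose(prox(V, 0.0), V)

    @pytest.mark.parametrize("prox", [prox_l1, prox_l21, prox_trace])
    def test_negative_tau_rejected(self, prox):
        with pytest.raises(ValueError, match="tau"):
            prox(np.ones((2, 2)), -0.1)

    def test_l21_small_row_zeroed(self):
        V = np.array([[0.1, 0.1], [3.0, 4.0]])
        out = prox_l21(V, 0.5)
        assert np.all(out[0] == 0.0)
        assert np.allclose(out[1], V[1] * (1 - 0.5 / 5.0))

    def test_l1_soft_threshold_values(self):
        V = np.array([[1.5, -0.3, 0.0]])
        assert np.allclose(prox_l1(V, 0.5), [[1.0, 0.0, 0.0]])

    def test_l1_matches_scalar_minimizer(self):
        """The l1 prox is separable: each entry solves a 1-D problem that a
        bounded scalar optimizer can settle to high precision."""
        from scipy.optimize import minimize_scalar

        rng = np.random.default_rng(11)
        tau = 0.5
        V = rng.normal(size=(4, 3))
        ours = prox_l1(V, tau)
        for v, w in zip(V.ravel(), ours.ravel()):
            res = minimize_scalar(
                lambda x: tau * abs(x) + 0.5 * (x - v) ** 2,
                bounds=(-abs(v) - 1, abs(v) + 1), method="bounded",
                options={"xatol": 1e-12})
            assert w == pytest.approx(res.x, abs=1e-6)

    def test_l21_matches_rowwise_minimizer(self):
        """Each gene row solves an independent small problem."""
        rng = np.random.default_rng(12)
        tau = 0.5
        V = rng.normal(size=(4, 3)) * 0.6   # some rows near the threshold
        ours = prox_l21(V, tau)
        for r in range(4):
            v = V[r]

            def obj(w):
                return tau * np.linalg.norm(w) + 0.5 * np.sum((w - v) ** 2)

            res = oracle_minimize(obj, 3, restarts=10, x0=v)
            assert obj(ours[r]) <= res.fun + 1e-10
            assert np.allclose(ours[r], res.x, atol=1e-5)

    def test_trace_matches_numeric_minimizer(self):
        """Singular-value thresholding agrees with a generic minimizer of
        tau*||W||_* + ||W - V||_F^2 / 2 on the objective scale."""
        rng = np.random.default_rng(13)
        tau = 0.5
        for _ in range(2):
            V = rng.normal(size=(4, 3))
            ours = prox_trace(V, tau)

            def obj(z):
                W = z.reshape(4, 3)
                return (tau * np.linalg.svd(W, compute_uv=False).sum()
                        + 0.5 * np.sum((W - V) ** 2))

            res = oracle_minimize(obj, 12, restarts=14, x0=V.ravel())
            assert obj(ours.ravel()) <= res.fun + 1e-10
            assert abs(obj(ours.ravel()) - res.fun) < 1e-6


class TestFit:
    def test_net_lam0_equals_independent_fits(self):
        """With no coupling the objective separates over tasks.

        Uses overlapping classes so each task's unpenalized logistic MLE is
        finite and unique.
        """
        tasks = make_tasks(t=2, p=3, n=50, seed=5, noise=2.0)
        joint = fit(tasks, "NET", lam=0.0, opts=TIGHT)
        for i, (X, Y) in enumerate(tasks):
            single = fit([(X, Y)], "NET", lam=0.0, opts=TIGHT)
            assert np.allclose(joint.W[:, i], single.W[:, 0], atol=1e-4)
            assert joint.C[i] == pytest.approx(single.C[0], abs=1e-4)

    def test_net_huge_lam_collapses_columns(self, tiny_tasks):
        m = fit(tiny_tasks, "NET", lam=1e6, opts=TIGHT)
        spread = np.abs(m.W - m.W.mean(axis=1, keepdims=True)).max()
        assert spread < 1e-3

    @pytest.mark.parametrize("form,alpha", [
        ("NET", None), ("SNET", 0.5), ("L21", None),
        ("EN", 0.5), ("TRACE", None),
    ])
    def test_objective_trace_monotone(self, tiny_tasks, form, alpha):
        m = fit(tiny_tasks, form, lam=0.1, alpha=alpha, opts=TIGHT)
        trace = np.asarray(m.objective_trace)
        assert np.all(np.diff(trace) <= 1e-10)
        assert m.converged

    def test_smooth_gradient_small_at_solution(self, tiny_tasks):
        """Convexity certificate for the fully smooth NET objective."""
        m = fit(tiny_tasks, "NET", lam=0.5, opts=TIGHT)
        _, gW, gC = logistic_loss(m.W, m.C, tiny_tasks)
        _, gP = penalty_net(m.W, 0.5)
        assert np.abs(gW + gP).max() < 1e-4
        assert np.abs(gC).max() < 1e-4

    @pytest.mark.parametrize("form,alpha", [("SNET", 0.3), ("L21", None),
                                            ("EN", 0.3), ("LR_L1", None)])
    def test_large_lam_gives_exact_zeros(self, tiny_tasks, form, alpha):
        data = pool(tiny_tasks) if form == "LR_L1" else tiny_tasks
        m = fit(data, form, lam=50.0, alpha=alpha, opts=TIGHT)
        assert np.all(m.W == 0.0)   # true zeros, not small floats

    def test_task_permutation_equivariance(self, tiny_tasks):
        m12 = fit(tiny_tasks, "NET", lam=0.3, opts=TIGHT)
        m21 = fit(tiny_tasks[::-1], "NET", lam=0.3, opts=TIGHT)
        assert np.allclose(m12.W, m21.W[:, ::-1], atol=1e-5)
        assert m12.objective_trace[-1] == pytest.approx(
            m21.objective_trace[-1], rel=1e-6)

    def test_alpha_required_for_composite(self, tiny_tasks):
        with pytest.raises(ValueError, match="alpha"):
            fit(tiny_tasks, "SNET", lam=0.1)

    def test_unknown_formulation(self, tiny_tasks):
        with pytest.raises(ValueError, match="formulation"):
            fit(tiny_tasks, "RIDGE", lam=0.1)


class TestPredict:
    def test_zero_model_gives_half_and_control(self):
        m = solvers.MTLModel(W=np.zeros((3, 2)), C=np.zeros(2),
                             formulation="NET", lam=0.0)
        prob, labels = predict(m, np.random.default_rng(0).normal(size=(5, 3)))
        assert np.allclose(prob, 0.5)
        assert np.all(labels == -1.0)   # tie goes to control

    def test_identical_columns_equal_single_task(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=3)
        m2 = solvers.MTLModel(W=np.column_stack([w, w]), C=np.array([0.2, 0.2]),
                              formulation="NET", lam=0.0)
        m1 = solvers.MTLModel(W=w[:, None], C=np.array([0.2]),
                              formulation="NET", lam=0.0)
        X = rng.normal(size=(6, 3))
        assert np.allclose(predict(m2, X)[0], predict(m1, X)[0])

    def test_matches_hand_computed_mean_of_sigmoids(self):
        rng = np.random.default_rng(2)
        W = rng.normal(size=(4, 2))
        C = rng.normal(size=2)
        X = rng.normal(size=(5, 4))
        m = solvers.MTLModel(W=W, C=C, formulation="NET", lam=0.0)
        prob, _ = predict(m, X)
        by_hand = np.mean([1 / (1 + np.exp(-(X @ W[:, i] + C[i])))
                           for i in range(2)], axis=0)
        assert np.allclose(prob, by_hand, atol=1e-12)

    def test_dimension_mismatch(self):
        m = solvers.MTLModel(W=np.zeros((3, 1)), C=np.zeros(1),
                             formulation="NET", lam=0.0)
        with pytest.raises(ValueError, match="features"):
            predict(m, np.zeros((2, 4)))


def test_grids_match_published_ranges():
    """Lambda grids are powers of ten over the documented exponent ranges."""
    assert np.allclose(np.log10(GRIDS["NET"]["lam"]), np.arange(-6, 3))
    assert np.allclose(np.log10(GRIDS["SNET"]["lam"]), np.arange(-6, 3))
    assert np.allclose(np.log10(GRIDS["L21"]["lam"]),
                       np.round(np.arange(-6, 0.01, 0.1), 10))
    assert np.allclose(np.log10(GRIDS["EN"]["lam"]),
                       np.round(np.arange(-6, 0.01, 0.1), 10))
    assert np.allclose(np.log10(GRIDS["TRACE"]["lam"]),
                       np.round(np.arange(-6, 1.01, 0.1), 10))
    assert np.allclose(GRIDS["SNET"]["alpha"], np.round(np.arange(0, 1.01, 0.1), 10))
    assert np.allclose(np.log10(GRIDS["LR_L1"]["lam"]),
                       np.round(np.arange(-10, 1.01, 0.5), 10))
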