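import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mtgsel import (
    draw_task_subsets,
    gradient,
    objective,
    predict_labels,
    predict_proba,
    prox_l21,
    select_genes,
    smooth_loss,
)
from mtgsel.mtl_core import MultiTaskModel, predict_logits

from conftest import random_tasks
from oracles import prox_l21_bruteforce

matrices = arrays(
    float,
    st.tuples(st.integers(1, 6), st.integers(2, 3)),
    elements=st.floats(-10, 10, allow_nan=False),
)


class TestSmoothLoss:
    def test_zero_weights_give_m_log2(self, small_tasks):
        W = np.zeros((small_tasks.d, small_tasks.m))
        c = np.zeros(small_tasks.m)
        assert smooth_loss(small_tasks, W, c) == pytest.approx(
            small_tasks.m * np.log(2)
        )

    def test_scalar_hand_computation(self):
        # one task, one sample x=(1), y=+1, w=(1), c=0 -> log(1+e^-1)
        from mtgsel import TaskCollection

        tc = TaskCollection(
            X=np.array([[1.0]]), y=np.array([1]), subsets=np.array([[0]]), eta=1.0
        )
        val = smooth_loss(tc, np.array([[1.0]]), np.array([0.0]))
        assert val == pytest.approx(np.log1p(np.exp(-1.0)))

    def test_huge_margins_no_overflow(self):
        X = np.array([[1000.0], [1000.0], [1000.0]])
        y = np.array([1, 1, -1])
        tc = draw_task_subsets(X, m=1, eta=1.0, seed=0, y=y)
        # y=+1 samples have margin +1000 (no contribution); y=-1 has -1000
        val = smooth_loss(tc, np.array([[1.0]]), np.array([0.0]))
        assert np.isfinite(val)
        assert val == pytest.approx(1000.0 / 3, rel=1e-6)

    def test_dimension_mismatch_rejected(self, small_tasks):
        with pytest.raises(ValueError):
            smooth_loss(small_tasks, np.zeros((2, 2)), np.zeros(2))


class TestObjective:
    def test_lambda_zero_equals_smooth_loss(self, small_tasks):
        rng = np.random.default_rng(0)
        W = rng.standard_normal((small_tasks.d, small_tasks.m))
        c = rng.standard_normal(small_tasks.m)
        assert objective(small_tasks, W, c, 0.0) == pytest.approx(
            smooth_loss(small_tasks, W, c)
        )

    def test_single_row_penalty(self):
        # one nonzero row (3, 4) across 2 tasks adds exactly 5 at lambda = 1
        tc = random_tasks(n=10, d=4, m=2, seed=1)
        W = np.zeros((4, 2))
        W[2] = [3.0, 4.0]
        c = np.zeros(2)
        assert objective(tc, W, c, 1.0) == pytest.approx(
            smooth_loss(tc, W, c) + 5.0
        )

    def test_negative_lambda_rejected(self, small_tasks):
        with pytest.raises(ValueError):
            objective(
                small_tasks,
                np.zeros((small_tasks.d, small_tasks.m)),
                np.zeros(small_tasks.m),
                -0.1,
            )

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_convexity_interpolation(self, alpha):
        tc = random_tasks(n=12, d=5, m=2, seed=2)
        rng = np.random.default_rng(3)
        lam = 0.7
        for _ in range(5):
            U, V = rng.standard_normal((2, 5, 2))
            cu, cv = rng.standard_normal((2, 2))
            mid = objective(
                tc, alpha * U + (1 - alpha) * V, alpha * cu + (1 - alpha) * cv, lam
            )
            assert mid <= alpha * objective(tc, U, cu, lam) + (1 - alpha) * objective(
                tc, V, cv, lam
            ) + 1e-10


class TestGradient:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        tc = random_tasks(
            n=int(rng.integers(8, 20)), d=int(rng.integers(2, 8)),
            m=int(rng.integers(1, 4)), seed=seed,
        )
        W = rng.standard_normal((tc.d, tc.m))
        c = rng.standard_normal(tc.m)
        Gw, gc = gradient(tc, W, c)
        h = 1e-5
        for j in range(tc.d):
            for k in range(tc.m):
                Wp, Wm = W.copy(), W.copy()
                Wp[j, k] += h
                Wm[j, k] -= h
                fd = (smooth_loss(tc, Wp, c) - smooth_loss(tc, Wm, c)) / (2 * h)
                assert abs(fd - Gw[j, k]) < 1e-5
        for k in range(tc.m):
            cp, cm = c.copy(), c.copy()
            cp[k] += h
            cm[k] -= h
            fd = (smooth_loss(tc, W, cp) - smooth_loss(tc, W, cm)) / (2 * h)
            assert abs(fd - gc[k]) < 1e-5

    def test_saturated_margins_give_zero_gradient(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10, 2))
        y = np.sign(X[:, 0]).astype(int)
        tc = draw_task_subsets(X, m=1, eta=1.0, seed=0, y=y)
        W = np.array([[1000.0], [0.0]])  # perfectly separates with huge margin
        Gw, gc = gradient(tc, W, np.zeros(1))
        assert np.abs(Gw).max() < 1e-12
        assert np.abs(gc).max() < 1e-12

    def test_block_structure_across_tasks(self):
        """Perturbing task 2's data leaves the gradient column of task 1 unchanged."""
        tc = random_tasks(n=14, d=4, m=2, seed=4)
        rng = np.random.default_rng(5)
        W = rng.standard_normal((4, 2))
        c = rng.standard_normal(2)
        Gw1, _ = gradient(tc, W, c)
        X2 = tc.X.copy()
        X2[tc.subsets[1]] += rng.standard_normal((tc.nk, 4))
        # rebuild collection keeping task 0's rows untouched
        only_task0_rows = np.setdiff1d(tc.subsets[1], tc.subsets[0])
        X2[tc.subsets[0]] = tc.X[tc.subsets[0]]
        X2[only_task0_rows] += 0.0
        tc2 = type(tc)(X=X2, y=tc.y, subsets=tc.subsets, eta=tc.eta)
        Gw2, _ = gradient(tc2, W, c)
        np.testing.assert_allclose(Gw2[:, 0], Gw1[:, 0])


class TestProxL21:
    def test_theta_zero_is_identity(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((5, 3))
        np.testing.assert_array_equal(prox_l21(A, 0.0), A)

    def test_boundary_row_killed(self):
        A = np.array([[3.0, 4.0]])
        np.testing.assert_array_equal(prox_l21(A, 5.0), np.zeros((1, 2)))

    def test_row_shrunk_by_closed_form(self):
        A = np.array([[3.0, 4.0]])
        np.testing.assert_allclose(prox_l21(A, 1.0), [[2.4, 3.2]])

    def test_negative_theta_rejected(self):
        with pytest.raises(ValueError):
            prox_l21(np.ones((2, 2)), -1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_minimizer(self, seed):
        rng = np.random.default_rng(seed)
        ncol = int(rng.integers(2, 4))
        a = rng.uniform(-4, 4, size=ncol)
        theta = float(rng.uniform(0, 4))
        ours = prox_l21(a[None, :], theta)[0]
        brute = prox_l21_bruteforce(a, theta)
        assert np.abs(ours - brute).max() < 1e-4

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(matrices, st.floats(0, 5))
    def test_support_is_rows_above_theta(self, A, theta):
        out = prox_l21(A, theta)
        norms = np.linalg.norm(A, axis=1)
        out_norms = np.linalg.norm(out, axis=1)
        assert np.array_equal(out_norms > 0, norms > theta)

    def test_nonexpansive(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            A, B = rng.standard_normal((2, 6, 3)) * rng.uniform(0.1, 5)
            theta = float(rng.uniform(0, 3))
            lhs = np.linalg.norm(prox_l21(A, theta) - prox_l21(B, theta))
            assert lhs <= np.linalg.norm(A - B) + 1e-12


class TestPrediction:
    def test_zero_model_gives_half(self):
        X = np.random.default_rng(0).standard_normal((7, 4))
        p = predict_proba(np.zeros((4, 3)), np.zeros(3), X)
        np.testing.assert_array_equal(p, np.full(7, 0.5))

    def test_identical_tasks_equal_single_task(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((9, 5))
        w = rng.standard_normal(5)
        b = 0.3
        W = np.tile(w[:, None], (1, 4))
        p_multi = predict_proba(W, np.full(4, b), X)
        p_single = predict_proba(w[:, None], np.array([b]), X)
        np.testing.assert_allclose(p_multi, p_single)

    def test_opposite_logits_average_to_half(self):
        # m=2 with per-sample logits (+2, -2) -> mean logit 0 -> p = 0.5
        X = np.array([[1.0]])
        W = np.array([[2.0, -2.0]])
        p = predict_proba(W, np.zeros(2), X)
        assert p[0] == pytest.approx(0.5)

    def test_threshold_strictness(self):
        # p = 0.5 at tau = 0.5 maps to class 0 (strict inequality)
        X = np.zeros((1, 2))
        lab = predict_labels(np.zeros((2, 1)), np.zeros(1), X, tau=0.5)
        assert lab.tolist() == [0]

    def test_extreme_threshold(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 3))
        W = rng.standard_normal((3, 2))
        labels = predict_labels(W, np.zeros(2), X, tau=0.99)
        p = predict_proba(W, np.zeros(2), X)
        assert np.array_equal(labels, (p > 0.99).astype(int))

    def test_gene_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="genes"):
            predict_logits(np.zeros((4, 2)), np.zeros(2), np.zeros((3, 5)))

    def test_bad_tau_rejected(self):
        with pytest.raises(ValueError):
            predict_labels(np.zeros((2, 1)), np.zeros(1), np.zeros((1, 2)), tau=1.0)


class TestSelectGenes:
    def test_zero_matrix_selects_nothing(self):
        assert select_genes(np.zeros((5, 3))).n_selected == 0

    def test_tolerance_excludes_float_noise(self):
        W = np.zeros((3, 2))
        W[1, 0] = 1e-12
        W[2, 0] = 0.3
        sel = select_genes(W, tol=1e-8)
        assert sel.selected.tolist() == [2]

    def test_sorted_by_descending_norm(self):
        W = np.diag([1.0, 3.0, 2.0])
        sel = select_genes(W)
        assert sel.selected.tolist() == [1, 2, 0]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(matrices, st.floats(0, 2), st.floats(0, 2))
    def test_selection_nested_in_tolerance(self, W, a, b):
        lo, hi = min(a, b), max(a, b)
        assert set(select_genes(W, hi).selected) <= set(select_genes(W, lo).selected)


class TestModelSerialization:
    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        model = MultiTaskModel(
            W=rng.standard_normal((4, 2)),
            c=rng.standard_normal(2),
            lam=0.3,
            gene_ids=["a", "b", "c", "d"],
            feature_mean=rng.standard_normal(4),
            feature_scale=np.abs(rng.standard_normal(4)) + 0.5,
        )
        path = tmp_path / "model.json"
        model.save(path)
        back = MultiTaskModel.load(path)
        np.testing.assert_allclose(back.W, model.W)
        np.testing.assert_allclose(back.feature_scale, model.feature_scale)
        X = rng.standard_normal((6, 4))
        np.testing.assert_allclose(back.predict_proba(X), model.predict_proba(X))
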