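"""Association model: similarity/Laplacian construction, objective and
gradient, the group-soft-threshold prox, and the accelerated solver."""

import numpy as np
import pytest
from scipy.optimize import minimize

from phenet.model import (
    MultiModalDataset,
    RegularizationConfig,
    build_laplacian,
    build_similarity,
    fit,
    lambda_max,
    objective_value,
    predict,
    prox_l21,
    smooth_gradient,
)
from conftest import make_dataset


def stage_graphs(data):
    S = build_similarity(data.stages)
    return [build_laplacian(S) for _ in range(data.n_modalities)]


def objective_scalar_loop(W, data, L, lam1, lam2):
    """Naive term-by-term evaluation of the penalised objective."""
    total = 0.0
    for m, Xm in enumerate(data.X):
        for i in range(data.n_subjects):
            total += 0.5 * (data.y[i] - float(Xm[i] @ W[:, m])) ** 2
        z = np.array([float(Xm[i] @ W[:, m]) for i in range(data.n_subjects)])
        total += lam2 * sum(z[i] * L[i, j] * z[j]
                            for i in range(len(z)) for j in range(len(z)))
    for j in range(data.n_features):
        total += lam1 * np.sqrt(sum(W[j, m] ** 2 for m in range(W.shape[1])))
    return total


class TestSimilarityAndLaplacian:
    def test_same_class_rule(self):
        S = build_similarity(["HC", "HC", "MD"])
        np.testing.assert_array_equal(S, [[1, 1, 0], [1, 1, 0], [0, 0, 1]])

    def test_degenerate_label_sets(self):
        np.testing.assert_array_equal(build_similarity(["MD"] * 4),
                                      np.ones((4, 4)))
        np.testing.assert_array_equal(build_similarity(["a", "b", "c"]),
                                      np.eye(3))
        with pytest.raises(ValueError, match="empty"):
            build_similarity([])

    def test_identity_similarity_gives_zero_laplacian(self):
        g = build_laplacian(np.eye(4))
        np.testing.assert_array_equal(g.L, np.zeros((4, 4)))

    def test_all_ones_similarity(self):
        g = build_laplacian(np.ones((3, 3)))
        np.testing.assert_array_equal(g.L, 3 * np.eye(3) - np.ones((3, 3)))

    def test_rows_sum_zero_and_psd(self, rng):
        stages = list(rng.choice(["HC", "MD", "SD"], 15))
        g = build_laplacian(build_similarity(stages))
        np.testing.assert_allclose(g.L @ np.ones(15), 0, atol=1e-12)
        assert np.linalg.eigvalsh(g.L).min() >= -1e-10

    def test_asymmetric_raises(self):
        S = np.eye(3)
        S[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            build_laplacian(S)

    def test_pairwise_distance_identity(self, rng):
        """The Laplacian quadratic equals the pairwise same-class distance sum:
        sum_ij (w'x_i - w'x_j)^2 S_ij == 2 w'X'LXw."""
        for _ in range(5):
            n, d = int(rng.integers(5, 30)), int(rng.integers(2, 15))
            X = rng.standard_normal((n, d))
            w = rng.standard_normal(d)
            stages = list(rng.choice(["HC", "MD", "SD"], n))
            S = build_similarity(stages)
            L = build_laplacian(S).L
            z = X @ w
            lhs = sum((z[i] - z[j]) ** 2 * S[i, j]
                      for i in range(n) for j in range(n))
            rhs = 2.0 * z @ L @ z
            assert lhs == pytest.approx(rhs, rel=1e-8)


class TestObjectiveAndGradient:
    def test_zero_weights_leave_only_loss(self, tiny_dataset):
        cfg = RegularizationConfig(lambda1=1.0, lambda2=1.0)
        g = stage_graphs(tiny_dataset)
        W = np.zeros((tiny_dataset.n_features, tiny_dataset.n_modalities))
        expected = 0.5 * tiny_dataset.n_modalities * tiny_dataset.y @ tiny_dataset.y
        assert objective_value(W, tiny_dataset, g, cfg) == pytest.approx(expected)

    def test_exact_fit_objective_vanishes(self, rng):
        X = rng.standard_normal((12, 4))
        w = rng.standard_normal(4)
        data = MultiModalDataset(X=[X], y=X @ w, stages=["HC"] * 12,
                                 roi_names=list("abcd"), modalities=["node"])
        cfg = RegularizationConfig(lambda1=0.0, lambda2=0.0, variant="SM")
        assert objective_value(w[:, None], data, None, cfg) == pytest.approx(0.0, abs=1e-18)

    def test_matches_scalar_loop_oracle(self, rng, tiny_dataset):
        cfg = RegularizationConfig(lambda1=0.7, lambda2=0.4)
        g = stage_graphs(tiny_dataset)
        W = rng.standard_normal((tiny_dataset.n_features,
                                 tiny_dataset.n_modalities))
        got = objective_value(W, tiny_dataset, g, cfg)
        want = objective_scalar_loop(W, tiny_dataset, g[0].L, 0.7, 0.4)
        assert got == pytest.approx(want, rel=1e-10)

    def test_gradient_at_zero(self, tiny_dataset):
        cfg = RegularizationConfig(lambda1=0.0, lambda2=0.9)
        g = stage_graphs(tiny_dataset)
        W = np.zeros((tiny_dataset.n_features, tiny_dataset.n_modalities))
        G = smooth_gradient(W, tiny_dataset, g, cfg)
        for m, Xm in enumerate(tiny_dataset.X):
            np.testing.assert_allclose(G[:, m], -Xm.T @ tiny_dataset.y)

    def test_gradient_matches_finite_differences(self, rng, tiny_dataset):
        cfg = RegularizationConfig(lambda1=0.0, lambda2=0.3)
        g = stage_graphs(tiny_dataset)
        W = 0.1 * rng.standard_normal((tiny_dataset.n_features,
                                       tiny_dataset.n_modalities))
        G = smooth_gradient(W, tiny_dataset, g, cfg)
        eps = 1e-6
        for j, m in [(0, 0), (3, 1), (7, 0)]:
            Wp, Wm = W.copy(), W.copy()
            Wp[j, m] += eps
            Wm[j, m] -= eps
            fd = (objective_value(Wp, tiny_dataset, g, cfg)
                  - objective_value(Wm, tiny_dataset, g, cfg)) / (2 * eps)
            assert G[j, m] == pytest.approx(fd, rel=1e-5, abs=1e-6)


class TestProx:
    def test_row_shrinkage_example(self):
        V = np.array([[3.0, 4.0]])
        np.testing.assert_allclose(prox_l21(V, 2.5), [[1.5, 2.0]])

    def test_full_shrinkage_and_identity(self, rng):
        V = rng.standard_normal((6, 3))
        norms = np.linalg.norm(V, axis=1)
        out = prox_l21(V, norms.max() + 0.1)
        np.testing.assert_array_equal(out, np.zeros_like(V))
        np.testing.assert_array_equal(prox_l21(V, 0.0), V)

    def test_negative_tau_raises(self):
        with pytest.raises(ValueError):
            prox_l21(np.ones((2, 2)), -1.0)

    def test_variational_inequality(self, rng):
        """prox output beats random perturbations on the prox objective."""
        V = rng.standard_normal((5, 2))
        tau = 0.8
        P = prox_l21(V, tau)

        def F(X):
            return 0.5 * np.sum((X - V) ** 2) + tau * np.linalg.norm(X, axis=1).sum()

        for _ in range(100):
            X = P + 0.5 * rng.standard_normal(P.shape)
            assert F(P) <= F(X) + 1e-12

    def test_matches_numeric_row_minimizer(self, rng):
        for _ in range(10):
            v = rng.standard_normal(3)
            tau = float(rng.uniform(0, 2))
            got = prox_l21(v[None, :], tau)[0]
            res = minimize(lambda x: 0.5 * np.sum((x - v) ** 2)
                           + tau * np.linalg.norm(x), v, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14,
                                    "maxiter": 5000})
            f_got = 0.5 * np.sum((got - v) ** 2) + tau * np.linalg.norm(got)
            assert f_got <= res.fun + 1e-9


class TestFit:
    def test_zero_solution_above_lambda_max(self, tiny_dataset):
        lm = lambda_max(tiny_dataset)
        cfg = RegularizationConfig(lambda1=lm * 1.001, lambda2=0.5)
        m = fit(tiny_dataset, cfg=cfg, standardize=False)
        assert np.all(m.W == 0)

    def test_all_rows_active_without_sparsity(self, tiny_dataset):
        cfg = RegularizationConfig(lambda1=0.0, lambda2=0.0, tol=1e-10,
                                   max_iter=5000)
        m = fit(tiny_dataset, cfg=cfg)
        assert len(m.selected_rows()) == tiny_dataset.n_features

    def test_unpenalized_single_modality_matches_ols(self, rng):
        X = rng.standard_normal((50, 6))
        y = rng.standard_normal(50)
        data = MultiModalDataset(X=[X], y=y, stages=["HC"] * 50,
                                 roi_names=[f"r{j}" for j in range(6)],
                                 modalities=["node"])
        cfg = RegularizationConfig(lambda1=0.0, variant="SM", tol=1e-14,
                                   max_iter=20000)
        m = fit(data, cfg=cfg, standardize=False)
        w_ols = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(m.W[:, 0], w_ols, atol=1e-6)

    def test_objective_trace_monotone(self, tiny_dataset):
        cfg = RegularizationConfig(lambda1=0.3, lambda2=0.2, tol=1e-12,
                                   max_iter=2000)
        m = fit(tiny_dataset, cfg=cfg)
        assert np.all(np.diff(m.objective_trace) <= 1e-10)
        assert m.converged

    def test_msd_with_zero_lambda2_bitmatches_mm(self, tiny_dataset):
        a = fit(tiny_dataset, cfg=RegularizationConfig(
            lambda1=0.2, lambda2=0.0, variant="MSD-MM"))
        b = fit(tiny_dataset, cfg=RegularizationConfig(
            lambda1=0.2, lambda2=0.7, variant="MM"))  # lambda2 forced to 0
        np.testing.assert_array_equal(a.W, b.W)

    def test_cm_concatenates_features(self, tiny_dataset):
        m = fit(tiny_dataset, cfg=RegularizationConfig(lambda1=0.1,
                                                       variant="CM"))
        assert m.W.shape == (2 * tiny_dataset.n_features, 1)

    def test_sm_rejects_multimodal_input(self, tiny_dataset):
        with pytest.raises(ValueError, match="single-modality"):
            fit(tiny_dataset, cfg=RegularizationConfig(variant="SM"))

    def test_near_oracle_objective_on_tiny_instance(self, rng):
        data = make_dataset(rng, n=20, d=8, m=2)
        cfg = RegularizationConfig(lambda1=0.1, lambda2=0.05, tol=1e-12,
                                   max_iter=5000)
        m = fit(data, cfg=cfg, standardize=False)
        # plain proximal-gradient oracle, long run
        from phenet.model import build_laplacian, build_similarity
        L = build_laplacian(build_similarity(data.stages)).L
        A = np.stack([Xm.T @ Xm + 2 * cfg.lambda2 * (Xm.T @ (L @ Xm))
                      for Xm in data.X])
        B = np.column_stack([Xm.T @ data.y for Xm in data.X])
        step = 1.0 / max(np.linalg.eigvalsh(Am).max() for Am in A)
        W = np.zeros((8, 2))
        for _ in range(200_000):
            G = np.einsum("mij,jm->im", A, W) - B
            Wn = prox_l21(W - step * G, step * cfg.lambda1)
            if np.max(np.abs(Wn - W)) < 1e-15:
                W = Wn
                break
            W = Wn
        graphs = [build_laplacian(build_similarity(data.stages))] * 2
        f_fista = objective_value(m.W, data, graphs, cfg)
        f_oracle = objective_value(W, data, graphs, cfg)
        assert f_fista <= f_oracle * (1 + 1e-7)


class TestPredict:
    def test_zero_weights_predict_training_mean(self, tiny_dataset):
        lm = lambda_max(tiny_dataset)
        m = fit(tiny_dataset, cfg=RegularizationConfig(lambda1=2 * lm))
        for p in predict(m, tiny_dataset.X):
            np.testing.assert_allclose(p, tiny_dataset.y.mean())

    def test_matches_rowwise_dot_product(self, rng, tiny_dataset):
        m = fit(tiny_dataset, cfg=RegularizationConfig(lambda1=0.05,
                                                       lambda2=0.02))
        Xnew = [rng.standard_normal((7, tiny_dataset.n_features))
                for _ in range(2)]
        preds = predict(m, Xnew)
        for mm, (Xm, p) in enumerate(zip(Xnew, preds)):
            Xt = (Xm - m.feature_means[mm]) / m.feature_scales[mm]
            for i in range(7):
                want = sum(Xt[i, j] * m.W[j, mm]
                           for j in range(tiny_dataset.n_features))
                assert p[i] == pytest.approx(want + m.intercepts[mm])

    def test_prediction_invariant_to_feature_order(self, rng, tiny_dataset):
        cfg = RegularizationConfig(lambda1=0.1, lambda2=0.1, tol=1e-12,
                                   max_iter=5000)
        m1 = fit(tiny_dataset, cfg=cfg)
        perm = rng.permutation(tiny_dataset.n_features)
        permuted = MultiModalDataset(
            X=[Xm[:, perm] for Xm in tiny_dataset.X], y=tiny_dataset.y,
            stages=tiny_dataset.stages,
            roi_names=[tiny_dataset.roi_names[j] for j in perm],
            modalities=tiny_dataset.modalities)
        m2 = fit(permuted, cfg=cfg)
        p1 = predict(m1, tiny_dataset.X)
        p2 = predict(m2, permuted.X)
        for a, b in zip(p1, p2):
            np.testing.assert_allclose(a, b, atol=1e-6)

    def test_dimension_mismatch_raises(self, tiny_dataset):
        m = fit(tiny_dataset, cfg=RegularizationConfig(lambda1=0.1))
        with pytest.raises(ValueError, match="columns"):
            predict(m, [np.zeros((3, 5)), np.zeros((3, 5))])
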