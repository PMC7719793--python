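import numpy as np
import pytest
from dataclasses import replace

from smmtransfer import (Hyperparams, MatrixDataset, TrialMatrix,
                         build_dual_coefficients, decision_function, fit,
                         fit_linear_svm, load_model, nuclear_subgradient_residual,
                         objective, predict, save_model, svt, update_S,
                         update_multiplier)
from conftest import random_separable_dataset


class TestBuildDualCoefficients:
    def test_hand_evaluated_scalar_case(self):
        X = np.array([[[2.0]], [[-1.0]]])
        y = np.array([1.0, -1.0])
        Z = np.zeros((1, 1))
        p = build_dual_coefficients(X, y, Z, Z, None, lam=0.0, rho=1.0, C=1.0)
        np.testing.assert_allclose(p.K, 0.5 * np.array([[4.0, 2.0], [2.0, 1.0]]))
        np.testing.assert_allclose(p.H, [1.0, 1.0])

    def test_h_is_ones_when_state_zero(self, rng):
        X = rng.standard_normal((5, 3, 2))
        y = np.where(rng.random(5) < 0.5, 1.0, -1.0)
        Z = np.zeros((3, 2))
        p = build_dual_coefficients(X, y, Z, Z, None, lam=0.0, rho=2.0, C=1.0)
        np.testing.assert_allclose(p.H, np.ones(5))

    def test_K_is_psd(self, rng):
        X = rng.standard_normal((8, 3, 3))
        y = np.where(rng.random(8) < 0.5, 1.0, -1.0)
        S = rng.standard_normal((3, 3))
        L = rng.standard_normal((3, 3))
        Ws = rng.standard_normal((3, 3))
        p = build_dual_coefficients(X, y, L, S, Ws, lam=0.3, rho=1.5, C=1.0)
        assert np.linalg.eigvalsh(p.K).min() > -1e-10

    def test_source_shape_mismatch_rejected(self, rng):
        X = rng.standard_normal((4, 3, 3))
        y = np.array([1.0, -1.0, 1.0, -1.0])
        Z = np.zeros((3, 3))
        with pytest.raises(ValueError):
            build_dual_coefficients(X, y, Z, Z, np.zeros((2, 2)), 0.5, 1.0, 1.0)


class TestUpdateS:
    def test_tau_zero_closed_form(self, rng):
        W = rng.standard_normal((4, 3))
        L = rng.standard_normal((4, 3))
        np.testing.assert_allclose(update_S(W, L, 0.0, 2.0), W - L / 2.0, atol=1e-12)

    def test_reduces_to_plain_svt(self, rng):
        W = rng.standard_normal((4, 3))
        np.testing.assert_allclose(update_S(W, np.zeros_like(W), 0.3, 1.0),
                                   svt(W, 0.3), atol=1e-12)

    def test_prox_objective_minimized(self, rng):
        # the update solves min tau*||S||_* + tr(L^T S) + rho/2 ||S-W||_F^2;
        # check the subgradient optimality condition and random perturbations
        W = rng.standard_normal((5, 4))
        L = rng.standard_normal((5, 4))
        tau, rho = 0.3, 2.0
        S = update_S(W, L, tau, rho)

        def J(M):
            from smmtransfer import nuclear_norm
            return (tau * nuclear_norm(M) + np.sum(L * M)
                    + rho / 2 * np.linalg.norm(M - W, "fro") ** 2)

        G = (rho * W - L - rho * S) / tau  # must be in the subdifferential at S
        assert nuclear_subgradient_residual(S, G) <= 1e-8
        base = J(S)
        for _ in range(50):
            R = rng.standard_normal(S.shape)
            R /= np.linalg.norm(R, "fro")
            assert J(S + 1e-4 * R) >= base - 1e-12


class TestUpdateMultiplier:
    def test_unchanged_at_zero_residual(self, rng):
        W = rng.standard_normal((3, 3))
        L = rng.standard_normal((3, 3))
        np.testing.assert_array_equal(update_multiplier(L, W, W, 1.7), L)

    def test_accumulates_residual(self, rng):
        E = rng.standard_normal((2, 2))
        W = rng.standard_normal((2, 2))
        np.testing.assert_allclose(update_multiplier(np.zeros((2, 2)), W + E, W, 1.0), E)


class TestObjective:
    def test_zero_model_all_hinges_one(self, rng):
        data, _ = random_separable_dataset(0, n=12)
        X, y = data.labeled()
        hyper = Hyperparams(C=2.5)
        assert abs(objective(X, y, np.zeros((4, 4)), 0.0, hyper) - 2.5 * 12) < 1e-12

    def test_transfer_term_vanishes_at_source(self, rng):
        Ws = rng.standard_normal((3, 3))
        X = rng.standard_normal((4, 3, 3))
        y = np.array([1.0, -1.0, 1.0, -1.0])
        hyper = Hyperparams(C=1e-30, tau=0.0, lam=5.0)
        val = objective(X, y, Ws, 0.0, hyper, W_source=Ws)
        assert abs(val - 0.5 * np.sum(Ws * Ws)) < 1e-12

    def test_fit_output_is_local_minimum(self, default_hyper):
        data, _ = random_separable_dataset(3, n=20)
        X, y = data.labeled()
        model = fit(data, default_hyper)
        base = objective(X, y, model.W, model.b, default_hyper)
        g = np.random.default_rng(0)
        for _ in range(100):
            dW = 1e-3 * g.standard_normal(model.W.shape)
            db = 1e-3 * g.standard_normal()
            assert objective(X, y, model.W + dW, model.b + db, default_hyper) \
                >= base - 1e-9


class TestFit:
    @pytest.mark.parametrize("seed", range(20))
    def test_tau_zero_matches_vectorized_linear_svm(self, seed):
        # Frobenius inner product == dot product of flattened trials, so
        # the tau=0, lam=0 machine must agree with a linear SVM
        data, _ = random_separable_dataset(seed, n=30, p=4, q=4)
        X, _ = data.labeled()
        hyper = Hyperparams(C=1.0, tau=0.0, tol_obj=1e-12, tol_primal=1e-8,
                            max_iter=2000)
        model = fit(data, hyper)
        ref = fit_linear_svm(data, C=1.0)
        dec_m = decision_function(model, X)
        dec_v = ref.decision_function(X.reshape(len(X), -1)).ravel()
        assert np.max(np.abs(dec_m - dec_v)) < 1e-4

    def test_tau_zero_matches_sklearn_oracle(self):
        from sklearn.svm import SVC
        data, _ = random_separable_dataset(42, n=30, p=4, q=4)
        X, y = data.labeled()
        hyper = Hyperparams(C=1.0, tau=0.0, tol_obj=1e-12, tol_primal=1e-8,
                            max_iter=2000)
        model = fit(data, hyper)
        sv = SVC(kernel="linear", C=1.0, tol=1e-9).fit(X.reshape(30, -1), y)
        assert np.max(np.abs(decision_function(model, X)
                             - sv.decision_function(X.reshape(30, -1)))) < 1e-4

    def test_lambda_zero_continuity(self, rng):
        data, _ = random_separable_dataset(5, n=20)
        X, y = data.labeled()
        hyper0 = Hyperparams(C=1.0, tau=0.1, lam=0.0)
        m0 = fit(data, hyper0)
        Ws = rng.standard_normal((4, 4))
        m1 = fit(data, replace(hyper0, lam=1e-12), W_source=Ws)
        o0 = objective(X, y, m0.W, m0.b, hyper0)
        o1 = objective(X, y, m1.W, m1.b, hyper0)
        assert abs(o0 - o1) < 1e-6

    def test_huge_lambda_pins_W_to_source(self, rng):
        data, _ = random_separable_dataset(6, n=10)
        Ws = rng.standard_normal((4, 4))
        m = fit(data, Hyperparams(C=1.0, tau=0.1, lam=1e8), W_source=Ws)
        assert np.linalg.norm(m.W - Ws, "fro") / np.linalg.norm(Ws, "fro") < 1e-6

    def test_nuclear_penalty_shrinks_rank(self):
        # with a strong nuclear penalty the fitted W has rank <= the
        # unpenalized fit's rank in nearly all seeds
        import scipy.linalg as sla
        wins = 0
        for seed in range(50):
            data, _ = random_separable_dataset(seed, n=20, p=4, q=4)
            m0 = fit(data, Hyperparams(C=1.0, tau=0.0))
            m1 = fit(data, Hyperparams(C=1.0, tau=0.5))
            def nrank(W):
                s = sla.svdvals(W)
                return int(np.sum(s > 1e-6 * s[0])) if s[0] > 0 else 0
            wins += nrank(m1.W) <= nrank(m0.W)
        assert wins >= 45

    def test_separable_data_perfect_training_accuracy(self):
        data, _ = random_separable_dataset(9, n=40, margin=0.3)
        X, y = data.labeled()
        m = fit(data, Hyperparams(C=10.0, tau=0.01))
        assert np.mean(predict(m, X) == y) == 1.0

    def test_convergence_residuals_and_trace(self, default_hyper):
        for seed in (0, 1, 2):
            data, _ = random_separable_dataset(seed, n=25)
            m = fit(data, default_hyper)
            assert m.converged
            assert m.primal_residual <= default_hyper.tol_primal * max(
                1.0, np.linalg.norm(m.W, "fro"))
            assert m.stationarity_residual <= 1e-8
            assert m.kkt_residual <= 1e-6
            tr = np.array(m.objective_trace)
            if len(tr) > 6:
                assert np.all(np.diff(tr[5:]) <= 1e-10 * np.maximum(1.0, np.abs(tr[5:-1])))

    def test_accelerated_reaches_same_objective(self):
        data, _ = random_separable_dataset(13, n=25)
        X, y = data.labeled()
        hyper = Hyperparams(C=1.0, tau=0.2, tol_obj=1e-10)
        m_plain = fit(data, hyper)
        m_acc = fit(data, replace(hyper, accelerated=True))
        o_p = objective(X, y, m_plain.W, m_plain.b, hyper)
        o_a = objective(X, y, m_acc.W, m_acc.b, hyper)
        assert abs(o_p - o_a) < 1e-5

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((5, 3, 3))
        data = MatrixDataset.from_arrays(X, np.ones(5))
        with pytest.raises(ValueError):
            fit(data, Hyperparams())

    def test_lam_without_source_rejected(self):
        data, _ = random_separable_dataset(0, n=10)
        with pytest.raises(ValueError):
            fit(data, Hyperparams(lam=0.5))

    def test_arbitrary_binary_labels_roundtrip(self):
        data, _ = random_separable_dataset(2, n=20)
        X, y = data.labeled()
        relabeled = MatrixDataset.from_arrays(X, np.where(y > 0, 7.0, 3.0))
        m = fit(relabeled, Hyperparams(C=1.0, tau=0.1))
        yhat = predict(m, X)
        assert set(np.unique(yhat)) <= {7.0, 3.0}
        assert np.mean(yhat == np.where(y > 0, 7.0, 3.0)) > 0.9


class TestPrediction:
    def test_zero_W_positive_bias(self):
        from smmtransfer import FittedMatrixModel
        model = FittedMatrixModel(W=np.zeros((2, 2)), b=0.5, hyper=Hyperparams())
        X = np.random.default_rng(0).standard_normal((2, 2))
        assert decision_function(model, X) == 0.5
        assert predict(model, X) == 1.0

    def test_decision_equals_flattened_dot(self, rng):
        from smmtransfer import FittedMatrixModel
        W = rng.standard_normal((3, 4))
        model = FittedMatrixModel(W=W, b=0.2, hyper=Hyperparams())
        X = rng.standard_normal((3, 4))
        assert abs(decision_function(model, X)
                   - (W.ravel() @ X.ravel() + 0.2)) < 1e-12

    def test_shape_mismatch_rejected(self):
        from smmtransfer import FittedMatrixModel
        model = FittedMatrixModel(W=np.zeros((2, 2)), b=0.0, hyper=Hyperparams())
        with pytest.raises(ValueError):
            decision_function(model, np.zeros((3, 3)))


class TestSerialization:
    def test_roundtrip(self, tmp_path, rng):
        data, _ = random_separable_dataset(4, n=15)
        Ws = rng.standard_normal((4, 4))
        m = fit(data, Hyperparams(C=2.0, tau=0.05, lam=0.1), W_source=Ws)
        path = tmp_path / "model.json"
        save_model(m, path)
        m2 = load_model(path)
        np.testing.assert_allclose(m2.W, m.W, atol=1e-15, rtol=0)
        np.testing.assert_allclose(m2.W_source, Ws, atol=1e-15, rtol=0)
        assert m2.b == m.b
        assert m2.hyper == m.hyper
        assert m2.classes == m.classes
        assert m2.n_iter == m.n_iter and m2.converged == m.converged
        assert m2.objective_trace == m.objective_trace
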