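import copy

import numpy as np
import pytest

from tritask.data_io import AssociationMatrices
from tritask.model import (
    Hyperparams,
    augmented_lagrangian,
    fit,
    fit_single_task,
    load_checkpoint,
    objective_value,
    save_checkpoint,
    solve_coefficient,
    update_multipliers,
    update_primal,
    _update_J,
    _update_W,
)
from tritask.synthetic import SyntheticSpec, generate
from conftest import random_laplacian, random_state


def scalar_objective(state, A_p, A_n, L_U, L_V, h):
    """Element-wise loop re-implementation of the regularized loss."""
    m, n = A_p.shape
    k = state.U.shape[1]
    total = 0.0
    for A, R, use in ((A_p, state.R_p, h.use_p), (A_n, state.R_n, h.use_n)):
        if not use:
            continue
        for i in range(m):
            for j in range(n):
                pred = sum(state.U[i, a] * R[a, b] * state.V[j, b] for a in range(k) for b in range(k))
                total += 0.5 * (A[i, j] - pred) ** 2
        total += 0.5 * h.lam * sum(R[a, b] ** 2 for a in range(k) for b in range(k))
    total += 0.5 * h.alpha * sum(
        state.U[i, a] * L_U[i, j] * state.U[j, a]
        for i in range(m) for j in range(m) for a in range(k)
    )
    total += 0.5 * h.beta * sum(
        state.V[i, a] * L_V[i, j] * state.V[j, a]
        for i in range(n) for j in range(n) for a in range(k)
    )
    total += 0.5 * h.lam * (np.sum(state.U ** 2) + np.sum(state.V ** 2))
    return total


class TestObjective:
    def test_zero_factors(self, small_problem):
        A_p, A_n, L_U, L_V, hyper, state = small_problem
        zero = copy.deepcopy(state)
        for name in ("U", "V", "R_p", "R_n"):
            setattr(zero, name, np.zeros_like(getattr(zero, name)))
        expected = 0.5 * (np.linalg.norm(A_p) ** 2 + np.linalg.norm(A_n) ** 2)
        assert objective_value(zero, A_p, A_n, L_U, L_V, hyper) == pytest.approx(expected)

    def test_exact_factorization_no_regularization(self):
        rng = np.random.default_rng(0)
        m, n, k = 6, 5, 2
        state = random_state(rng, m, n, k)
        A_p = state.U @ state.R_p @ state.V.T
        A_n = state.U @ state.R_n @ state.V.T
        h = Hyperparams(k=k, alpha=0, beta=0, lam=0, seed=0)
        val = objective_value(state, A_p, A_n, np.zeros((m, m)), np.zeros((n, n)), h)
        assert val == pytest.approx(0.0, abs=1e-20)

    def test_matches_scalar_loop(self, small_problem):
        A_p, A_n, L_U, L_V, hyper, state = small_problem
        expected = scalar_objective(state, A_p, A_n, L_U, L_V, hyper)
        assert objective_value(state, A_p, A_n, L_U, L_V, hyper) == pytest.approx(expected, abs=1e-10)

    def test_single_task_drops_other_terms(self, small_problem):
        A_p, A_n, L_U, L_V, hyper, state = small_problem
        hp = Hyperparams(**{**hyper.__dict__, "mode": "single_task_p"})
        expected = scalar_objective(state, A_p, A_n, L_U, L_V, hp)
        assert objective_value(state, A_p, A_n, L_U, L_V, hp) == pytest.approx(expected, abs=1e-10)


class TestAugmentedLagrangian:
    def test_reduces_to_objective_on_feasible_point(self, small_problem):
        A_p, A_n, L_U, L_V, hyper, state = small_problem
        s = copy.deepcopy(state)
        s.J, s.W = s.V.copy(), s.U.copy()
        s.Y, s.Z = np.zeros_like(s.Y), np.zeros_like(s.Z)
        assert augmented_lagrangian(s, A_p, A_n, L_U, L_V, hyper) == pytest.approx(
            objective_value(s, A_p, A_n, L_U, L_V, hyper), abs=1e-10
        )

    def test_perturbing_J_adds_laplacian_and_penalty(self, small_problem):
        A_p, A_n, L_U, L_V, hyper, state = small_problem
        rng = np.random.default_rng(5)
        s = copy.deepcopy(state)
        s.J, s.W = s.V.copy(), s.U.copy()
        s.Y, s.Z = np.zeros_like(s.Y), np.zeros_like(s.Z)
        base = augmented_lagrangian(s, A_p, A_n, L_U, L_V, hyper)
        E = rng.normal(size=s.J.shape)
        s2 = copy.deepcopy(s)
        s2.J = s.V + E
        tr_diff = 0.5 * hyper.beta * (
            np.trace(s2.J.T @ L_V @ s2.J) - np.trace(s.V.T @ L_V @ s.V)
        )
        expected = base + tr_diff + 0.5 * s.rho2 * np.linalg.norm(E) ** 2
        assert augmented_lagrangian(s2, A_p, A_n, L_U, L_V, hyper) == pytest.approx(expected, abs=1e-9)

    def test_matches_scalar_loop(self, small_problem):
        A_p, A_n, L_U, L_V, hyper, state = small_problem
        expected = scalar_objective(state, A_p, A_n, L_U, L_V, hyper)
        # swap the Laplacian terms from U,V onto W,J and add multiplier/penalty terms
        expected -= 0.5 * hyper.alpha * np.trace(state.U.T @ L_U @ state.U)
        expected -= 0.5 * hyper.beta * np.trace(state.V.T @ L_V @ state.V)
        expected += 0.5 * hyper.alpha * np.trace(state.W.T @ L_U @ state.W)
        expected += 0.5 * hyper.beta * np.trace(state.J.T @ L_V @ state.J)
        expected += np.trace(state.Z.T @ (state.W - state.U))
        expected += 0.5 * state.rho1 * np.linalg.norm(state.W - state.U) ** 2
        expected += np.trace(state.Y.T @ (state.J - state.V))
        expected += 0.5 * state.rho2 * np.linalg.norm(state.J - state.V) ** 2
        assert augmented_lagrangian(state, A_p, A_n, L_U, L_V, hyper) == pytest.approx(expected, abs=1e-10)


class TestSolveCoefficient:
    def test_orthonormal_factors_no_ridge(self):
        rng = np.random.default_rng(0)
        m, n, k = 8, 7, 3
        U, _ = np.linalg.qr(rng.normal(size=(m, k)))
        V, _ = np.linalg.qr(rng.normal(size=(n, k)))
        A = rng.normal(size=(m, n))
        R = solve_coefficient(A, U, V, lam=0.0)
        assert np.allclose(R, U.T @ A @ V, atol=1e-8)

    def test_huge_ridge_shrinks_to_zero(self):
        rng = np.random.default_rng(1)
        U, V, A = rng.normal(size=(10, 3)), rng.normal(size=(8, 3)), rng.normal(size=(10, 8))
        R = solve_coefficient(A, U, V, lam=1e12)
        assert np.linalg.norm(R) <= 1e-6 * np.linalg.norm(U.T @ A @ V)

    def test_dense_kronecker_oracle(self):
        rng = np.random.default_rng(2)
        m, n, k, lam = 10, 8, 3, 0.5
        U, V, A = rng.normal(size=(m, k)), rng.normal(size=(n, k)), rng.normal(size=(m, n))
        R = solve_coefficient(A, U, V, lam=lam)
        K = np.kron(V.T @ V, U.T @ U) + lam * np.eye(k * k)
        expected = np.linalg.solve(K, (U.T @ A @ V).reshape(-1, order="F")).reshape(k, k, order="F")
        assert np.allclose(R, expected, atol=1e-8)

    def test_warm_start_accepted(self):
        rng = np.random.default_rng(3)
        U, V, A = rng.normal(size=(6, 2)), rng.normal(size=(5, 2)), rng.normal(size=(6, 5))
        cold = solve_coefficient(A, U, V, lam=0.3)
        warm = solve_coefficient(A, U, V, lam=0.3, x0=cold)
        assert np.allclose(cold, warm, atol=1e-8)

    def test_nonconvergence_warns(self):
        rng = np.random.default_rng(4)
        U, V, A = rng.normal(size=(9, 4)), rng.normal(size=(9, 4)), rng.normal(size=(9, 9))
        with pytest.warns(RuntimeWarning, match="CG"):
            solve_coefficient(A, U, V, lam=0.0, cg_max_iter=1, cg_tol=1e-14)


def numerical_gradient(fun, X, h=1e-6):
    G = np.zeros_like(X)
    it = np.nditer(X, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = X[idx]
        X[idx] = orig + h
        fp = fun()
        X[idx] = orig - h
        fm = fun()
        X[idx] = orig
        G[idx] = (fp - fm) / (2 * h)
    return G


class TestPrimalUpdates:
    def test_J_is_V_when_beta_zero(self, small_problem):
        A_p, A_n, L_U, L_V, hyper, state = small_problem
        J = _update_J(state.V, np.zeros_like(state.Y), L_V, beta=0.0, rho2=state.rho2)
        assert np.allclose(J, state.V, atol=1e-12)

    def test_W_is_U_when_alpha_zero(self, small_problem):
        A_p, A_n, L_U, L_V, hyper, state = small_problem
        W = _update_W(state.U, np.zeros_like(state.Z), L_U, alpha=0.0, rho1=state.rho1)
        assert np.allclose(W, state.U, atol=1e-12)

    @pytest.mark.parametrize("var", ["J", "W", "U", "V"])
    def test_each_update_zeroes_its_gradient(self, small_problem, var):
        A_p, A_n, L_U, L_V, hyper, state = small_problem
        s = copy.deepcopy(state)
        # apply updates sequentially up to and including `var`, then check
        # the finite-difference gradient of the augmented Lagrangian w.r.t. it
        order = ["J", "W", "U", "V"]
        full = copy.deepcopy(s)
        update_primal(full, A_p, A_n, L_U, L_V, hyper)
        for name in order[: order.index(var) + 1]:
            setattr(s, name, getattr(full, name))
        X = getattr(s, var)
        G = numerical_gradient(lambda: augmented_lagrangian(s, A_p, A_n, L_U, L_V, hyper), X)
        scale = 1.0 + np.linalg.norm(X)
        assert np.linalg.norm(G) <= 1e-6 * scale


class TestMultipliers:
    def test_zero_residuals_leave_multipliers(self, small_problem):
        *_, hyper, state = small_problem
        s = copy.deepcopy(state)
        s.J, s.W = s.V.copy(), s.U.copy()
        Y0, Z0, r1 = s.Y.copy(), s.Z.copy(), s.rho1
        update_multipliers(s, hyper)
        assert np.array_equal(s.Y, Y0) and np.array_equal(s.Z, Z0)
        assert s.rho1 == pytest.approx(hyper.mu * r1)

    def test_growth_factor(self, small_problem):
        *_, hyper, state = small_problem
        s = copy.deepcopy(state)
        s.rho1 = s.rho2 = 1.0
        update_multipliers(s, hyper)
        assert s.rho1 == pytest.approx(1.1)

    def test_cap(self, small_problem):
        *_, hyper, state = small_problem
        s = copy.deepcopy(state)
        s.rho1 = s.rho2 = hyper.rho_cap
        update_multipliers(s, hyper)
        assert s.rho1 == hyper.rho_cap and s.rho2 == hyper.rho_cap


@pytest.fixture(scope="module")
def planted_instance():
    return generate(SyntheticSpec(m=40, n=50, k_true=3, density_p=0.05,
                                  density_n=0.08, noise=0.0, seed=11))


class TestFit:
    def test_seeded_determinism(self, planted_instance):
        inst = planted_instance
        hp = Hyperparams(k=3, alpha=1, beta=1, lam=1, seed=42, max_iter=30)
        s1, sc1 = fit(inst.matrices.A_p, inst.matrices.A_n, inst.W_r, inst.W_d, hp)
        s2, sc2 = fit(inst.matrices.A_p, inst.matrices.A_n, inst.W_r, inst.W_d, hp)
        assert np.array_equal(sc1.S_p, sc2.S_p) and np.array_equal(sc1.S_n, sc2.S_n)
        assert s1.history["objective"] == s2.history["objective"]

    def test_planted_reconstruction(self):
        # noiseless planted binary matrices (scores rounded to {0,1}) are
        # near rank-k_true, so the fit should reconstruct them closely
        rng = np.random.default_rng(0)
        m, n, k = 40, 50, 3
        U = rng.uniform(0, 1, (m, k))
        V = rng.uniform(0, 1, (n, k))
        R_p = rng.uniform(0, 1.4, (k, k))
        R_n = rng.uniform(0, 1.4, (k, k))
        A_p = np.round(np.clip(U @ R_p @ V.T, 0, 1))
        A_n = np.round(np.clip(U @ R_n @ V.T, 0, 1))
        hp = Hyperparams(k=k, alpha=0, beta=0, lam=0.01, seed=0)
        _, scores = fit(A_p, A_n, np.eye(m), np.eye(n), hp)
        assert np.linalg.norm(A_p - scores.S_p) / np.linalg.norm(A_p) < 0.1
        assert np.linalg.norm(A_n - scores.S_n) / np.linalg.norm(A_n) < 0.1

    def test_row_permutation_equivariance(self, planted_instance):
        inst = planted_instance
        m = inst.matrices.shape[0]
        hp = Hyperparams(k=3, alpha=1, beta=1, lam=1, seed=3, max_iter=25)
        rng = np.random.default_rng(0)
        U0 = rng.uniform(0, 1, (m, 3))
        V0 = rng.uniform(0, 1, (inst.matrices.shape[1], 3))
        _, base = fit(inst.matrices.A_p, inst.matrices.A_n, inst.W_r.values,
                      inst.W_d.values, hp, init_U=U0, init_V=V0)
        perm = np.random.default_rng(9).permutation(m)
        _, permuted = fit(
            inst.matrices.A_p[perm], inst.matrices.A_n[perm],
            inst.W_r.values[np.ix_(perm, perm)], inst.W_d.values, hp,
            init_U=U0[perm], init_V=V0,
        )
        assert np.allclose(permuted.S_p, base.S_p[perm], atol=1e-8)
        assert np.allclose(permuted.S_n, base.S_n[perm], atol=1e-8)

    def test_k_too_large_rejected(self, planted_instance):
        inst = planted_instance
        hp = Hyperparams(k=40, seed=0)
        with pytest.raises(ValueError, match="k="):
            fit(inst.matrices.A_p, inst.matrices.A_n, inst.W_r, inst.W_d, hp)

    def test_objective_decreases_over_seeds(self):
        for seed in range(20):
            inst = generate(SyntheticSpec(m=25, n=30, k_true=2, density_p=0.08,
                                          density_n=0.1, seed=seed))
            hp = Hyperparams(k=2, alpha=1, beta=1, lam=1, seed=seed, max_iter=60)
            state, _ = fit(inst.matrices.A_p, inst.matrices.A_n, inst.W_r, inst.W_d, hp)
            hist = state.history["objective"]
            assert hist[-1] < hist[0]


class TestSingleTask:
    def test_shrinks_unused_coefficient(self, planted_instance):
        inst = planted_instance
        A_p = inst.matrices.A_p
        zeros = np.zeros_like(A_p)
        hp = Hyperparams(k=3, alpha=1, beta=1, lam=1, seed=5, max_iter=80)
        multi_state, _ = fit(A_p, zeros, inst.W_r, inst.W_d, hp)
        # with A_n = 0 the multi-task R_n only appears in its own ridge and
        # reconstruction of a zero matrix: it should be driven near zero
        assert np.linalg.norm(multi_state.R_n) < 0.1 * np.linalg.norm(multi_state.R_p)

    def test_k_one_converges(self, planted_instance):
        inst = planted_instance
        hp = Hyperparams(k=1, alpha=1, beta=1, lam=1, seed=0, max_iter=40)
        state, scores = fit_single_task(inst.matrices.A_p, inst.W_r, inst.W_d, hp, task="p")
        assert np.isfinite(scores).all()

    def test_seeded_determinism(self, planted_instance):
        inst = planted_instance
        hp = Hyperparams(k=2, alpha=1, beta=1, lam=1, seed=8, max_iter=30)
        _, s1 = fit_single_task(inst.matrices.A_n, inst.W_r, inst.W_d, hp, task="n")
        _, s2 = fit_single_task(inst.matrices.A_n, inst.W_r, inst.W_d, hp, task="n")
        assert np.array_equal(s1, s2)


class TestCheckpoint:
    def test_round_trip_bit_exact(self, planted_instance, tmp_path):
        inst = planted_instance
        hp = Hyperparams(k=3, alpha=1, beta=1, lam=1, seed=1, max_iter=15)
        state, _ = fit(inst.matrices.A_p, inst.matrices.A_n, inst.W_r, inst.W_d, hp)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(state, hp, path, drug_index=inst.matrices.drug_index,
                        disease_index=inst.matrices.disease_index)
        loaded, hp2, extra = load_checkpoint(path)
        for name in ("U", "V", "R_p", "R_n", "J", "W", "Y", "Z"):
            assert np.array_equal(getattr(loaded, name), getattr(state, name))
        assert loaded.rho1 == state.rho1 and loaded.rho2 == state.rho2
        assert hp2 == hp
        assert extra["drug_index"] == inst.matrices.drug_index
        assert loaded.history == state.history
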