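import numpy as np
import pytest

from grassvlad.errors import DegeneratePatchError, DimensionError
from grassvlad.hlds import (
    HLDSModel,
    _solve_qp,
    _solve_qp_active_set,
    fit_hlds,
    fit_hlds_batch,
    hosvd,
    largest_singular_value,
    least_squares_transition,
    mode_product,
    mode_unfold,
    stabilize_transition,
)
from grassvlad.patches import PatchTensor, rotation_variants

from conftest import rand_orth


def triple_mode_product(core, U1, U2, U3):
    """Independent reconstruction oracle via explicit summation."""
    out = np.einsum("abc,ia,jb,kc->ijk", core, U1, U2, U3)
    return out


class TestHosvd:
    def test_zero_tensor(self):
        tf = hosvd(np.zeros((4, 4, 3)))
        assert np.allclose(tf.core, 0)
        for U in (tf.U1, tf.U2, tf.U3):
            assert np.allclose(U.T @ U, np.eye(U.shape[1]), atol=1e-12)

    def test_rank_one_tensor_has_single_core_entry(self, rng):
        a, b = rng.standard_normal(5), rng.standard_normal(5)
        c = rng.standard_normal(3)
        Y = np.einsum("i,j,k->ijk", a, b, c)
        tf = hosvd(Y)
        expected = np.linalg.norm(a) * np.linalg.norm(b) * np.linalg.norm(c)
        core = np.abs(tf.core)
        assert core[0, 0, 0] == pytest.approx(expected, rel=1e-10)
        core[0, 0, 0] = 0
        assert np.max(core) < 1e-10 * expected

    @pytest.mark.parametrize("n", [4, 8, 16])
    def test_reconstruction_and_orthogonality(self, n):
        for seed in range(5):
            Y = np.random.default_rng(seed).standard_normal((n, n, 3))
            tf = hosvd(Y)
            rel = np.linalg.norm(tf.reconstruct() - Y) / np.linalg.norm(Y)
            assert rel <= 1e-10
            oracle = triple_mode_product(tf.core, tf.U1, tf.U2, tf.U3)
            assert np.allclose(oracle, Y, atol=1e-10)
            for U in (tf.U1, tf.U2, tf.U3):
                assert np.max(np.abs(U.T @ U - np.eye(U.shape[1]))) < 1e-10

    def test_mode3_unfolding_is_row_major_scan(self, rng):
        Y = rng.standard_normal((4, 4, 3))
        unf = mode_unfold(Y, 2)
        for i in range(4):
            for j in range(4):
                assert np.array_equal(unf[:, i * 4 + j], Y[i, j, :])

    def test_mode_product_matches_unfolding_identity(self, rng):
        # X = Y x3 U3^T  <=>  X_(3) = U3^T Y_(3)
        Y = rng.standard_normal((5, 5, 3))
        U3 = rand_orth(rng)
        X = mode_product(Y, U3.T, 2)
        assert np.allclose(mode_unfold(X, 2), U3.T @ mode_unfold(Y, 2))


class TestLeastSquares:
    def test_identity_dynamics(self, rng):
        X = rng.standard_normal((3, 20))
        A = least_squares_transition(X, X)
        assert np.allclose(A, np.eye(3), atol=1e-6)

    def test_zero_next_state(self, rng):
        X = rng.standard_normal((3, 20))
        assert np.allclose(least_squares_transition(X, np.zeros_like(X)), 0)

    def test_exact_recovery_of_simulated_dynamics(self):
        rng = np.random.default_rng(9)
        A_true = rand_orth(rng) * 0.9
        x = np.empty((3, 64))
        x[:, 0] = rng.standard_normal(3)
        for i in range(63):
            x[:, i + 1] = A_true @ x[:, i]
        A = least_squares_transition(x[:, :-1], x[:, 1:])
        assert np.max(np.abs(A - A_true)) < 1e-8

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(DimensionError):
            least_squares_transition(rng.standard_normal((3, 5)),
                                     rng.standard_normal((3, 6)))

    def test_ridge_formula_agrees_on_well_posed_problem(self, rng):
        Xp = rng.standard_normal((3, 50))
        Xn = rng.standard_normal((3, 50))
        a0 = least_squares_transition(Xp, Xn, ridge=0.0)
        a1 = least_squares_transition(Xp, Xn, ridge=1e-10)
        assert np.allclose(a0, a1, atol=1e-8)


class TestSingularValue:
    @pytest.mark.parametrize(
        "mat,expected",
        [(np.eye(3), 1.0), (np.zeros((3, 3)), 0.0),
         (np.diag([0.5, 0.2, 0.1]), 0.5)],
    )
    def test_known_values(self, mat, expected):
        assert largest_singular_value(mat) == pytest.approx(expected)


class TestStabilization:
    def _unstable_system(self, seed):
        r = np.random.default_rng(seed)
        A0 = rand_orth(r) * r.uniform(1.05, 2.0)
        Xp = r.standard_normal((3, 63))
        Xn = A0 @ Xp + 0.01 * r.standard_normal((3, 63))
        return least_squares_transition(Xp, Xn), Xp, Xn

    def test_stable_matrix_returned_unchanged(self, rng):
        A = rand_orth(rng) * 0.9
        Xp = rng.standard_normal((3, 20))
        out = stabilize_transition(A, Xp, A @ Xp)
        assert out is A

    def test_twice_identity_is_stabilized(self, rng):
        Xp = rng.standard_normal((3, 30))
        A = 2.0 * np.eye(3)
        out = stabilize_transition(A, Xp, A @ Xp)
        assert largest_singular_value(out) <= 1 + 1e-6

    def test_objective_beats_naive_rescaling(self):
        """Constraint-generation result is never worse than A / sigma_1(A)."""
        checked = 0
        for seed in range(30):
            A_ls, Xp, Xn = self._unstable_system(seed)
            s1 = largest_singular_value(A_ls)
            if s1 <= 1:
                continue
            checked += 1
            A_st = stabilize_transition(A_ls, Xp, Xn)
            assert largest_singular_value(A_st) <= 1 + 1e-6
            obj_st = np.linalg.norm(Xn - A_st @ Xp) ** 2
            obj_rs = np.linalg.norm(Xn - (A_ls / s1) @ Xp) ** 2
            assert obj_st <= obj_rs + 1e-9
        assert checked >= 25

    def test_active_set_qp_matches_slsqp(self):
        """Dual-route check of the QP solver on random strictly convex QPs."""
        from scipy.optimize import minimize

        for seed in range(20):
            r = np.random.default_rng(100 + seed)
            B = r.standard_normal((9, 9))
            P = B @ B.T + 0.5 * np.eye(9)
            q = r.standard_normal(9)
            G = r.standard_normal((4, 9))
            G /= np.linalg.norm(G, axis=1, keepdims=True)
            x0 = np.zeros(9)  # strictly feasible
            x_as = _solve_qp_active_set(P, q, G, x0)
            res = minimize(
                lambda a: a @ P @ a - 2 * q @ a, x0,
                jac=lambda a: 2 * P @ a - 2 * q,
                constraints=[{"type": "ineq", "fun": lambda a: 1 - G @ a,
                              "jac": lambda a: -G}],
                method="SLSQP", options={"ftol": 1e-14, "maxiter": 500},
            )
            f = lambda a: a @ P @ a - 2 * q @ a
            assert np.all(G @ x_as <= 1 + 1e-8)
            assert f(x_as) <= f(res.x) + 1e-7


class TestFitHlds:
    def _patch(self, seed=0, n=8):
        rng = np.random.default_rng(seed)
        return PatchTensor(rng.uniform(0.2, 0.8, (n, n, 3)), origin=(0, 0))

    def test_degenerate_patch_rejected(self):
        patch = PatchTensor(np.full((8, 8, 3), 0.3), origin=(0, 0))
        with pytest.raises(DegeneratePatchError):
            fit_hlds(patch)

    def test_constant_scan_sequence_rejected(self):
        v = np.full((8, 8, 3), 0.42)
        with pytest.raises(DegeneratePatchError):
            fit_hlds(PatchTensor(v, origin=(0, 0)))

    def test_model_contract(self):
        m = fit_hlds(self._patch())
        assert np.max(np.abs(m.C.T @ m.C - np.eye(3))) < 1e-10
        assert m.sigma1 == pytest.approx(largest_singular_value(m.A))
        if m.stabilized:
            assert m.sigma1 <= 1 + 1e-6

    def test_deterministic(self):
        a = fit_hlds(self._patch(3))
        b = fit_hlds(self._patch(3))
        assert np.array_equal(a.A, b.A) and np.array_equal(a.C, b.C)

    def test_rotation_variants_share_mapping_matrix(self):
        """Rotating a patch permutes the scan-order pixels, so the mode-3
        factor (and hence C) is unchanged while A generally differs."""
        variants = rotation_variants(self._patch(4))
        models = [fit_hlds(v) for v in variants]
        for m in models[1:]:
            assert np.allclose(m.C, models[0].C, atol=1e-9)
        assert not np.allclose(models[1].A, models[0].A, atol=1e-3)

    def test_observation_unfolding_identity(self):
        """Eq: Y_(3) = C X_(3) holds exactly for the identified model."""
        patch = self._patch(5)
        m = fit_hlds(patch)
        Yc = patch.values - patch.values.mean(axis=(0, 1))
        Y3 = Yc.reshape(-1, 3).T
        X3 = m.C.T @ Y3
        assert np.allclose(m.C @ X3, Y3, atol=1e-10)

    def test_batch_matches_single(self):
        patches = [self._patch(s) for s in range(6)]
        batch = fit_hlds_batch(patches)
        for p, mb in zip(patches, batch):
            ms = fit_hlds(p)
            assert np.allclose(ms.A, mb.A, atol=1e-12)
            assert np.allclose(ms.C, mb.C, atol=1e-12)
            assert ms.stabilized == mb.stabilized
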