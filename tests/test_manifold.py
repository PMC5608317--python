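import numpy as np
import pytest

from grassvlad.errors import (
    ConfigError,
    CutLocusError,
    DimensionError,
    RankDeficiencyError,
)
from grassvlad.hlds import HLDSModel
from grassvlad.manifold import (
    GrassmannPoint,
    TangentVector,
    distance_matrix,
    exp_map,
    geodesic_distance,
    k_medoids,
    karcher_mean,
    log_map,
    observability_subspace,
    pairwise_distances,
    principal_angles,
)

from conftest import perturb, rand_orth, rand_point


def line(angle):
    return GrassmannPoint(np.array([[np.cos(angle)], [np.sin(angle)]]))


def model(A, C):
    return HLDSModel(A=A, C=C, mean=np.zeros(3), stabilized=False,
                     sigma1=float(np.linalg.norm(A, 2)))


class TestObservabilitySubspace:
    def test_nilpotent_dynamics(self):
        pt = observability_subspace(model(np.zeros((3, 3)), np.eye(3)), m=3)
        expected = np.vstack([np.eye(3), np.zeros((6, 3))])
        assert np.allclose(pt.basis, expected)

    def test_identity_dynamics(self):
        pt = observability_subspace(model(np.eye(3), np.eye(3)), m=3)
        expected = GrassmannPoint(
            np.vstack([np.eye(3)] * 3) / np.sqrt(3))
        assert geodesic_distance(pt, expected) < 1e-10

    def test_state_basis_change_leaves_subspace_fixed(self, rng):
        A, C, T = rand_orth(rng) * 0.8, rand_orth(rng), rand_orth(rng)
        p1 = observability_subspace(model(A, C))
        p2 = observability_subspace(model(T.T @ A @ T, C @ T))
        assert geodesic_distance(p1, p2) < 1e-8

    def test_unobservable_system_raises(self):
        # C with a zero column span only; O = [C; CA; CA^2] rank 2.
        C = np.eye(3)
        C[:, 2] = 0
        with pytest.raises((RankDeficiencyError, DimensionError)):
            observability_subspace(model(np.zeros((3, 3)), C))


class TestLogExpMaps:
    def test_log_at_self_is_zero(self, rng):
        a = rand_point(rng)
        assert log_map(a, a).norm < 1e-10

    def test_line_in_plane_log_norm_is_angle(self):
        assert log_map(line(0.0), line(0.3)).norm == pytest.approx(0.3, abs=1e-12)

    def test_exp_of_zero_is_base(self, rng):
        a = rand_point(rng)
        out = exp_map(a, TangentVector(delta=np.zeros(a.shape), base=a))
        assert geodesic_distance(out, a) < 1e-12

    def test_exp_closed_form_on_circle(self):
        base = line(0.0)
        t = 0.7
        tangent = TangentVector(delta=np.array([[0.0], [t]]), base=base)
        out = exp_map(base, tangent)
        assert geodesic_distance(out, line(t)) < 1e-12

    def test_round_trip(self, rng):
        for _ in range(50):
            a, b = rand_point(rng), rand_point(rng)
            if principal_angles(a, b).max() > np.pi / 2 - 0.05:
                continue
            c = exp_map(a, log_map(a, b))
            assert geodesic_distance(c, b) <= 1e-6

    def test_exp_distance_equals_tangent_norm(self, rng):
        a = rand_point(rng)
        D = rng.standard_normal(a.shape) * 0.1
        D -= a.basis @ (a.basis.T @ D)
        out = exp_map(a, TangentVector(delta=D, base=a))
        assert geodesic_distance(a, out) == pytest.approx(
            np.linalg.norm(D), abs=1e-8)

    def test_horizontality_violation_rejected(self, rng):
        a = rand_point(rng)
        bad = TangentVector.__new__(TangentVector)
        bad.base = a
        bad.delta = a.basis * 0.5  # fully vertical
        with pytest.raises(ConfigError):
            exp_map(a, bad)

    def test_cut_locus_raises(self):
        with pytest.raises(CutLocusError):
            log_map(line(0.0), line(np.pi / 2))


class TestDistance:
    def test_identity(self, rng):
        a = rand_point(rng)
        assert geodesic_distance(a, a) == pytest.approx(0.0, abs=1e-10)

    def test_matches_principal_angle_oracle(self, rng):
        for _ in range(100):
            a, b = rand_point(rng), rand_point(rng)
            d = geodesic_distance(a, b)
            theta = np.arccos(np.clip(
                np.linalg.svd(a.basis.T @ b.basis, compute_uv=False), 0, 1))
            assert d == pytest.approx(np.sqrt((theta ** 2).sum()), abs=1e-6)

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(30):
            a, b, c = rand_point(rng), rand_point(rng), rand_point(rng)
            dab, dba = geodesic_distance(a, b), geodesic_distance(b, a)
            assert dab == pytest.approx(dba, abs=1e-8)
            assert dab <= geodesic_distance(a, c) + geodesic_distance(c, b) + 1e-8

    def test_basis_invariance(self, rng):
        a, b = rand_point(rng), rand_point(rng)
        Q = rand_orth(rng, 3)
        a2 = GrassmannPoint(a.basis @ Q)
        assert geodesic_distance(a, b) == pytest.approx(
            geodesic_distance(a2, b), abs=1e-10)

    def test_pairwise_matches_singles(self, rng):
        pts = [rand_point(rng) for _ in range(6)]
        D = pairwise_distances(pts, pts)
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                assert D[i, j] == pytest.approx(
                    geodesic_distance(pts[i], pts[j]), abs=1e-8)


class TestPrincipalAngles:
    def test_identical_subspaces(self, rng):
        a = rand_point(rng)
        assert np.allclose(principal_angles(a, a), 0, atol=1e-7)

    def test_orthogonal_block_bases(self):
        a = GrassmannPoint(np.vstack([np.eye(3), np.zeros((3, 3))]))
        b = GrassmannPoint(np.vstack([np.zeros((3, 3)), np.eye(3)]))
        assert np.allclose(principal_angles(a, b), np.pi / 2)

    def test_column_permutation_invariance(self, rng):
        a, b = rand_point(rng), rand_point(rng)
        perm = GrassmannPoint(b.basis[:, [2, 0, 1]])
        assert np.allclose(principal_angles(a, b),
                           principal_angles(a, perm), atol=1e-10)


class TestKarcherMean:
    def test_single_point(self, rng):
        a = rand_point(rng)
        assert geodesic_distance(karcher_mean([a]), a) < 1e-12

    def test_identical_points(self, rng):
        a = rand_point(rng)
        mu = karcher_mean([a, GrassmannPoint(a.basis.copy()), a])
        assert geodesic_distance(mu, a) < 1e-12

    def test_circular_closed_form(self):
        mu = karcher_mean([line(0.2), line(0.4)], tol=1e-9)
        angle = np.arctan2(abs(mu.basis[1, 0]), abs(mu.basis[0, 0]))
        assert angle == pytest.approx(0.3, abs=1e-6)

    def test_objective_not_worse_than_inputs_or_init(self, rng):
        for _ in range(5):
            center = rand_point(rng)
            pts = [perturb(center, rng, scale=0.2) for _ in range(8)]
            init = pts[0]
            mu = karcher_mean(pts, init=init)

            def objective(q):
                return sum(geodesic_distance(q, p) ** 2 for p in pts)

            best_input = min(objective(p) for p in pts)
            assert objective(mu) <= best_input + 1e-8
            assert objective(mu) <= objective(init) + 1e-8


class TestKMedoids:
    def test_k_equals_n(self, rng):
        pts = [rand_point(rng) for _ in range(5)]
        assert sorted(k_medoids(pts, 5, seed=0)) == list(range(5))

    def test_two_separated_bundles(self, rng):
        a = rand_point(rng)
        b = rand_point(rng)
        while geodesic_distance(a, b) < 1.0:
            b = rand_point(rng)
        pts = [perturb(a, rng, 0.03) for _ in range(6)] + \
              [perturb(b, rng, 0.03) for _ in range(6)]
        med = k_medoids(pts, 2, seed=1)
        sides = sorted(m // 6 for m in med)
        assert sides == [0, 1]

    def test_k_one_matches_brute_force(self, rng):
        pts = [rand_point(rng) for _ in range(7)]
        D = distance_matrix(pts)
        expected = int(np.argmin(D.sum(axis=1)))
        assert list(k_medoids(pts, 1, seed=3)) == [expected]

    def test_k_greater_than_n_rejected(self, rng):
        with pytest.raises(ConfigError):
            k_medoids([rand_point(rng)], 2, seed=0)
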