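"""Grassmann manifold geometry for observability subspaces.

An identified system (A, C) is embedded as the column span of its finite
observability matrix O = [C; CA; ...; CA^(m-1)], a point on the Grassmann
manifold Gr(p, r) of r-dimensional subspaces of R^p (p = 3m, r = 3 by
default).  The module provides the Riemannian toolbox: exponential and
inverse-exponential (log) maps, the arc-length geodesic distance
d = sqrt(sum of squared principal angles), Karcher means and k-medoids
clustering on a precomputed distance matrix.

Bases are representatives only: every operation is invariant under right
multiplication of an input basis by an orthogonal r x r matrix.  Pairs of
subspaces with a principal angle of pi/2 lie on the cut locus, where the log
map is undefined; such pairs raise :class:`CutLocusError` rather than
silently picking a branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from .errors import (
    ConfigError,
    ConvergenceError,
    CutLocusError,
    DimensionError,
    RankDeficiencyError,
)
from .hlds import HLDSModel, _fix_signs

CUT_LOCUS_COS = 1e-10  # cos(theta) below this => principal angle at pi/2


@dataclass
class GrassmannPoint:
    """A p x r orthonormal-column basis representing a subspace."""

    basis: np.ndarray
    m: Optional[int] = None

    def __post_init__(self):
        b = np.asarray(self.basis, dtype=np.float64)
        if b.ndim != 2 or b.shape[0] < b.shape[1]:
            raise DimensionError(f"basis must be tall p x r, got {b.shape}")
        if np.max(np.abs(b.T @ b - np.eye(b.shape[1]))) > 1e-8:
            raise DimensionError("basis columns are not orthonormal")
        self.basis = b

    @property
    def shape(self):
        return self.basis.shape


@dataclass
class TangentVector:
    """A horizontal tangent vector at ``base``: base' @ delta = 0."""

    delta: np.ndarray
    base: GrassmannPoint

    def __post_init__(self):
        d = np.asarray(self.delta, dtype=np.float64)
        if d.shape != self.base.shape:
            raise DimensionError("tangent shape must match base basis shape")
        self.delta = d

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.delta))


def _orthonormalize(M: np.ndarray) -> np.ndarray:
    """QR with the R diagonal forced positive (deterministic Gram-Schmidt)."""
    Q, R = np.linalg.qr(M)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q * signs


def observability_subspace(model: HLDSModel, m: int = 3) -> GrassmannPoint:
    """Grassmann point spanned by the observability matrix [C; CA; ...; CA^(m-1)]."""
    if m < 1:
        raise ConfigError("observability horizon m must be >= 1")
    C, A = model.C, model.A
    blocks = [C]
    for _ in range(m - 1):
        blocks.append(blocks[-1] @ A)
    O = np.vstack(blocks)
    r = C.shape[1]
    Q, R = np.linalg.qr(O)
    diag = np.abs(np.diag(R))
    scale = max(np.linalg.norm(O), 1.0)
    if np.min(diag) < 1e-10 * scale:
        raise RankDeficiencyError(
            f"observability matrix rank-deficient at horizon m={m}"
        )
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return GrassmannPoint(basis=Q * signs, m=m)


def observability_subspaces_batch(
    A: np.ndarray, C: np.ndarray, m: int = 3
) -> np.ndarray:
    """Vectorized observability embedding: (B,3,3),(B,3,3) -> (B, 3m, 3)."""
    blocks = [C]
    for _ in range(m - 1):
        blocks.append(blocks[-1] @ A)
    O = np.concatenate(blocks, axis=1)
    Q, R = np.linalg.qr(O)
    diag = np.abs(np.einsum("bii->bi", R))
    scale = np.maximum(np.linalg.norm(O, axis=(1, 2)), 1.0)
    if np.any(diag.min(axis=1) < 1e-10 * scale):
        bad = int(np.argmin(diag.min(axis=1) / scale))
        raise RankDeficiencyError(
            f"observability matrix {bad} rank-deficient at horizon m={m}"
        )
    signs = np.sign(np.einsum("bii->bi", R))
    signs[signs == 0] = 1.0
    return Q * signs[:, None, :]


# ---------------------------------------------------------------------------
# Metric structure
# ---------------------------------------------------------------------------

def principal_angles(a: GrassmannPoint, b: GrassmannPoint) -> np.ndarray:
    """Descending principal angles in [0, pi/2]: arccos of singular values of a'b."""
    if a.shape != b.shape:
        raise DimensionError("points must share (p, r) shape")
    sv = np.linalg.svd(a.basis.T @ b.basis, compute_uv=False)
    return np.arccos(np.clip(sv, 0.0, 1.0))


def log_map(base: GrassmannPoint, target: GrassmannPoint) -> TangentVector:
    """Inverse exponential map: the tangent vector at ``base`` whose geodesic
    reaches the subspace of ``target`` at unit time.

    Uses the standard thin-SVD construction: with M = base' target,
    T = (I - base base') target M^-1 = U S V', the tangent is
    U arctan(S) V' and the principal angles are arctan of the singular
    values of T.  Undefined (cut locus) when M is singular.
    """
    if base.shape != target.shape:
        raise DimensionError("points must share (p, r) shape")
    X, Y = base.basis, target.basis
    M = X.T @ Y
    sv = np.linalg.svd(M, compute_uv=False)
    if sv.min() < CUT_LOCUS_COS:
        raise CutLocusError("subspaces at a principal angle of pi/2: log map undefined")
    T = np.linalg.solve(M.T, Y.T).T  # Y M^{-1}
    T = T - X @ (X.T @ T)
    u, s, vt = np.linalg.svd(T, full_matrices=False)
    delta = (u * np.arctan(s)) @ vt
    return TangentVector(delta=delta, base=base)


def exp_map(base: GrassmannPoint, tangent: TangentVector) -> GrassmannPoint:
    """Point reached at unit time along the geodesic with initial velocity
    ``tangent`` (which must be horizontal at ``base``)."""
    if tangent.base is not base and not np.array_equal(
        tangent.base.basis, base.basis
    ):
        raise ConfigError("tangent vector is not rooted at the given base point")
    X, D = base.basis, tangent.delta
    if np.max(np.abs(X.T @ D)) > 1e-6:
        raise ConfigError("tangent vector violates the horizontal-space condition")
    u, s, vt = np.linalg.svd(D, full_matrices=False)
    Y = (X @ vt.T) * np.cos(s) @ vt + (u * np.sin(s)) @ vt
    return GrassmannPoint(basis=_orthonormalize(Y), m=base.m)


def geodesic_distance(a: GrassmannPoint, b: GrassmannPoint) -> float:
    """Arc-length distance ||log_map(b, a)||_F = sqrt(sum of squared
    principal angles); symmetric, zero iff the subspaces coincide."""
    return log_map(b, a).norm


# Batched helpers: the same metric computed through principal angles
# (mathematically identical, vectorized over many pairs).

def _stack(points: Union[np.ndarray, Sequence[GrassmannPoint]]) -> np.ndarray:
    if isinstance(points, np.ndarray):
        return points
    return np.stack([p.basis for p in points])


def pairwise_distances(
    points_a: Union[np.ndarray, Sequence[GrassmannPoint]],
    points_b: Union[np.ndarray, Sequence[GrassmannPoint]],
) -> np.ndarray:
    """(n, m) matrix of geodesic distances between two point sets."""
    Pa, Pb = _stack(points_a), _stack(points_b)
    prod = np.einsum("ipr,jps->ijrs", Pa, Pb)
    sv = np.linalg.svd(prod.reshape(-1, Pa.shape[2], Pb.shape[2]),
                       compute_uv=False)
    theta = np.arccos(np.clip(sv, 0.0, 1.0))
    return np.sqrt((theta ** 2).sum(axis=1)).reshape(Pa.shape[0], Pb.shape[0])


def distance_matrix(points: Union[np.ndarray, Sequence[GrassmannPoint]],
                    chunk: int = 512) -> np.ndarray:
    """Symmetric pairwise geodesic-distance matrix, computed in chunks."""
    P = _stack(points)
    n = P.shape[0]
    D = np.zeros((n, n))
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        D[i0:i1] = pairwise_distances(P[i0:i1], P)
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D


def _log_map_batch(base_basis: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Log map from one base to a stack of targets: (p,r), (n,p,r) -> (n,p,r)."""
    X = base_basis
    M = np.einsum("pr,nps->nrs", X, targets)
    sv = np.linalg.svd(M, compute_uv=False)
    if sv.min() < CUT_LOCUS_COS:
        raise CutLocusError("cut-locus pair encountered in batched log map")
    T = np.linalg.solve(M.transpose(0, 2, 1), targets.transpose(0, 2, 1))
    T = T.transpose(0, 2, 1)
    T = T - X @ (X.T @ T)
    u, s, vt = np.linalg.svd(T, full_matrices=False)
    return (u * np.arctan(s)[:, None, :]) @ vt


# ---------------------------------------------------------------------------
# Karcher means and k-medoids
# ---------------------------------------------------------------------------

def karcher_mean(
    points: Sequence[GrassmannPoint],
    init: Optional[GrassmannPoint] = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    step: float = 1.0,
) -> GrassmannPoint:
    """Riemannian center of mass via iterated tangent-space averaging.

    Iterates mu <- exp(mu, step * mean_i log(mu, p_i)) until the mean tangent
    norm drops below ``tol``; the result satisfies the first-order condition
    ||sum_i log(mu, p_i)||_F <= n * tol.
    """
    if len(points) == 0:
        raise ConfigError("karcher_mean requires at least one point")
    stack = _stack(points)
    mu = init if init is not None else points[0]
    residual = None
    for _ in range(max_iter):
        try:
            tangents = _log_map_batch(mu.basis, stack)
        except CutLocusError as exc:
            raise CutLocusError(
                f"cut-locus pair while averaging {len(points)} points: {exc}"
            ) from exc
        mean_t = tangents.mean(axis=0)
        residual = float(np.linalg.norm(mean_t))
        if residual <= tol:
            return mu
        mu = exp_map(mu, TangentVector(delta=step * mean_t, base=mu))
    raise ConvergenceError(
        f"Karcher mean: residual {residual:.3e} > tol {tol} after {max_iter} iterations",
        last_iterate=mu,
        residual=residual,
    )


def k_medoids(
    points: Union[Sequence[GrassmannPoint], np.ndarray],
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    dist: Optional[np.ndarray] = None,
) -> np.ndarray:
    """K-medoids on the precomputed geodesic-distance matrix.

    Initialized by a seeded farthest-point heuristic, then alternates nearest-
    medoid assignment with per-cluster medoid updates; the total within-
    cluster distance is non-increasing.  Deterministic given ``seed`` (ties
    broken by lowest index).  Returns the k medoid indices.
    """
    D = dist if dist is not None else distance_matrix(points)
    n = D.shape[0]
    if k > n:
        raise ConfigError(f"k={k} exceeds number of points n={n}")
    if k == n:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        d_near = D[:, medoids].min(axis=1)
        d_near[medoids] = -1.0
        medoids.append(int(np.argmax(d_near)))
    medoids = np.array(medoids)
    for _ in range(max_iter):
        assign = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for j in range(k):
            members = np.nonzero(assign == j)[0]
            if members.size == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new[j] = members[int(np.argmin(within))]
        if np.array_equal(new, medoids):
            break
        medoids = new
    return medoids
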