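"""Higher-order linear dynamical system identification for image patches.

Each N x N x 3 patch is treated as a 3-channel signal evolving over pixels in
row-major scan order, following the state-space model

    x(i+1) = A x(i) + noise,        I(i) = mean + C x(i) + noise,

with a 3-dimensional hidden state.  The mapping matrix ``C`` is taken to be
orthonormal and is identified as the mode-3 factor ``U3`` of the higher-order
SVD (Tucker decomposition) of the mean-subtracted patch tensor; the states are
then the columns of the mode-3 unfolding of the core-reduced tensor, which by
the exact identity ``X_(3) = U3^T Y_(3)`` need not be formed via the full
Tucker product.  The transition matrix ``A`` is the one-step least-squares
regression of consecutive states; if its largest singular value exceeds 1 it
is stabilized by constraint generation on a convex quadratic program.

The state sequences entering the regression are column-centered: subtracting
the empirical observation mean leaves an affine offset ``(A - I) x_bar`` in
the state recursion, and centering both sides removes it exactly, so that a
noiseless patch generated from a stable system is recovered to machine
precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .errors import (
    DegeneratePatchError,
    DimensionError,
    NumericalError,
    StabilizationError,
)
from .patches import PatchTensor, is_degenerate, patch_stack

DEFAULT_RIDGE = 0.0
PINV_RCOND = 1e-12
DEFAULT_STAB_TOL = 1e-6
DEFAULT_STAB_MAX_ITER = 50


# ---------------------------------------------------------------------------
# Tensor algebra
# ---------------------------------------------------------------------------

def mode_unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` unfolding: mode fibers as columns.

    For mode 3 (index 2) of an N x N x 3 tensor this yields the 3 x N^2
    matrix whose column j is the pixel at row-major scan position j.
    """
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def mode_product(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """j-mode product: multiply ``matrix`` along axis ``mode`` of ``tensor``."""
    return np.moveaxis(
        np.tensordot(matrix, tensor, axes=(1, mode)), 0, mode
    )


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Flip column signs so each column's largest-magnitude entry is positive.

    Removes the SVD sign ambiguity; deterministic across runs and platforms.
    Works on a single (p, r) matrix or a stacked (B, p, r) array.
    """
    u = np.array(u, copy=True)
    if u.ndim == 2:
        idx = np.argmax(np.abs(u), axis=0)
        signs = np.sign(u[idx, np.arange(u.shape[1])])
        signs[signs == 0] = 1.0
        return u * signs
    idx = np.argmax(np.abs(u), axis=1)  # (B, r)
    picked = np.take_along_axis(u, idx[:, None, :], axis=1)[:, 0, :]
    signs = np.sign(picked)
    signs[signs == 0] = 1.0
    return u * signs[:, None, :]


@dataclass
class TuckerFactors:
    """Higher-order SVD factors: Y = core x1 U1 x2 U2 x3 U3."""

    core: np.ndarray
    U1: np.ndarray
    U2: np.ndarray
    U3: np.ndarray

    def reconstruct(self) -> np.ndarray:
        out = mode_product(self.core, self.U1, 0)
        out = mode_product(out, self.U2, 1)
        return mode_product(out, self.U3, 2)


def hosvd(Y: np.ndarray) -> TuckerFactors:
    """Higher-order SVD of an N x N x 3 tensor.

    Each factor ``U_j`` holds the left singular vectors of the mode-j
    unfolding, sign-fixed for determinism; the core is the tensor multiplied
    by the factor transposes along every mode.
    """
    Y = np.asarray(Y, dtype=np.float64)
    if not np.all(np.isfinite(Y)):
        raise NumericalError("hosvd: non-finite input tensor")
    if Y.ndim != 3:
        raise DimensionError(f"hosvd expects a 3rd-order tensor, got ndim={Y.ndim}")
    factors = []
    for mode in range(3):
        unf = mode_unfold(Y, mode)
        u, _, _ = np.linalg.svd(unf, full_matrices=True)
        factors.append(_fix_signs(u))
    U1, U2, U3 = factors
    core = mode_product(Y, U1.T, 0)
    core = mode_product(core, U2.T, 1)
    core = mode_product(core, U3.T, 2)
    return TuckerFactors(core=core, U1=U1, U2=U2, U3=U3)


# ---------------------------------------------------------------------------
# Transition estimation
# ---------------------------------------------------------------------------

def least_squares_transition(
    X_prev: np.ndarray, X_next: np.ndarray, ridge: float = DEFAULT_RIDGE
) -> np.ndarray:
    """One-step least-squares transition minimizing ||X_next - A X_prev||_F^2.

    With ``ridge > 0`` solves the regularized normal equations
    A = Xn Xp^T (Xp Xp^T + ridge I)^-1.  With ``ridge = 0`` (default) the
    minimum-norm solution A = Xn pinv(Xp) is used with a *relative* singular-
    value cutoff: weakly excited but noiseless trajectories are then recovered
    exactly, which an absolute ridge cannot do, while genuine rank deficiency
    is still guarded.
    """
    X_prev = np.asarray(X_prev, dtype=np.float64)
    X_next = np.asarray(X_next, dtype=np.float64)
    if X_prev.shape != X_next.shape or X_prev.ndim != 2:
        raise DimensionError(
            f"state matrices must share shape, got {X_prev.shape} vs {X_next.shape}"
        )
    if ridge < 0:
        raise NumericalError("ridge must be >= 0")
    if ridge > 0:
        d = X_prev.shape[0]
        gram = X_prev @ X_prev.T + ridge * np.eye(d)
        cross = X_next @ X_prev.T
        # A = cross @ inv(gram); gram is symmetric.
        return np.linalg.solve(gram, cross.T).T
    return X_next @ np.linalg.pinv(X_prev, rcond=PINV_RCOND)


def largest_singular_value(A: np.ndarray) -> float:
    """sigma_1(A); an upper bound on the spectral radius, so sigma_1 <= 1
    certifies |lambda_1(A)| <= 1."""
    A = np.asarray(A, dtype=np.float64)
    if not np.all(np.isfinite(A)):
        raise NumericalError("non-finite matrix")
    if A.size == 0:
        return 0.0
    return float(np.linalg.svd(A, compute_uv=False)[0])


# ---------------------------------------------------------------------------
# Stabilization: constraint-generation QP
# ---------------------------------------------------------------------------

def _solve_qp_active_set(
    P: np.ndarray,
    q: np.ndarray,
    G: np.ndarray,
    x0: np.ndarray,
    tol: float = 1e-11,
    max_iter: int = 200,
) -> np.ndarray:
    """Minimize x'Px - 2q'x subject to Gx <= 1, from a feasible start x0.

    Textbook primal active-set method; the problem is tiny (9 variables, a
    handful of constraints) so KKT systems are solved directly.
    """
    n = P.shape[0]
    x = np.asarray(x0, dtype=np.float64).copy()
    m = G.shape[0]
    gx = G @ x
    work = list(np.nonzero(gx > 1 - 1e-12)[0])
    for _ in range(max_iter):
        W = np.array(work, dtype=int)
        nw = len(W)
        kkt = np.zeros((n + nw, n + nw))
        kkt[:n, :n] = 2.0 * P
        rhs = np.concatenate([2.0 * q, np.ones(nw)])
        if nw:
            kkt[:n, n:] = G[W].T
            kkt[n:, :n] = G[W]
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
        x_eq, lam = sol[:n], sol[n:]
        d = x_eq - x
        if np.linalg.norm(d) <= tol * max(1.0, np.linalg.norm(x)):
            if nw == 0 or lam.min() >= -1e-9:
                return x_eq if nw == 0 else x
            work.pop(int(np.argmin(lam)))
            continue
        # Longest feasible step toward the equality-QP solution.
        t = 1.0
        blocking = -1
        for i in range(m):
            if i in work:
                continue
            gd = G[i] @ d
            if gd > 1e-14:
                ti = (1.0 - G[i] @ x) / gd
                if ti < t:
                    t, blocking = ti, i
        x = x + max(t, 0.0) * d
        if blocking >= 0 and t < 1.0:
            work.append(blocking)
    raise NumericalError("active-set QP did not converge")


def _solve_qp(P: np.ndarray, q: np.ndarray, G: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Active-set QP with a scipy SLSQP fallback."""
    try:
        return _solve_qp_active_set(P, q, G, x0)
    except NumericalError:
        res = minimize(
            lambda a: a @ P @ a - 2.0 * q @ a,
            x0,
            jac=lambda a: 2.0 * P @ a - 2.0 * q,
            constraints=[{"type": "ineq", "fun": lambda a: 1.0 - G @ a,
                          "jac": lambda a: -G}],
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14},
        )
        return res.x


def stabilize_transition(
    A: np.ndarray,
    X_prev: np.ndarray,
    X_next: np.ndarray,
    tol: float = DEFAULT_STAB_TOL,
    max_iter: int = DEFAULT_STAB_MAX_ITER,
) -> np.ndarray:
    """Return a transition matrix with sigma_1 <= 1 + tol.

    If ``A`` is already stable it is returned unchanged.  Otherwise the
    least-squares objective ||X_next - A X_prev||_F^2 is re-minimized under
    accumulated linear constraints g' vec(A) <= 1 with g = vec(u1 v1') built
    from the top singular pair of each visited iterate.  Since
    <u1 v1', B> <= sigma_1(B) for any B, every matrix with sigma_1 <= 1 stays
    feasible, so the result is never worse (in objective) than the naive
    rescaling A / sigma_1(A).
    """
    A = np.asarray(A, dtype=np.float64)
    if not np.all(np.isfinite(A)):
        raise NumericalError("stabilize_transition: non-finite A")
    s1 = largest_singular_value(A)
    if s1 <= 1.0 + tol:
        return A
    Xp = np.asarray(X_prev, dtype=np.float64)
    Xn = np.asarray(X_next, dtype=np.float64)
    d = A.shape[0]
    P = np.kron(np.eye(d), Xp @ Xp.T) + 1e-12 * np.eye(d * d)
    q = (Xn @ Xp.T).ravel()
    constraints: List[np.ndarray] = []
    A_cur = A
    for _ in range(max_iter):
        u, s, vt = np.linalg.svd(A_cur)
        constraints.append(np.outer(u[:, 0], vt[0]).ravel())
        G = np.stack(constraints)
        x0 = A_cur.ravel() / largest_singular_value(A_cur)
        alpha = _solve_qp(P, q, G, x0)
        A_cur = alpha.reshape(d, d)
        s1 = largest_singular_value(A_cur)
        if s1 <= 1.0 + tol:
            return A_cur
    raise StabilizationError(
        f"stabilization did not reach sigma_1 <= 1+{tol} in {max_iter} iterations",
        last_iterate=A_cur,
        residual=s1 - 1.0,
    )


# ---------------------------------------------------------------------------
# Per-patch model
# ---------------------------------------------------------------------------

@dataclass
class HLDSModel:
    """Identified patch descriptor: transition A, orthonormal mapping C,
    per-channel mean, stabilization outcome and scan direction."""

    A: np.ndarray
    C: np.ndarray
    mean: np.ndarray
    stabilized: bool
    sigma1: float
    direction: int = 0


def _center_columns(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=-1, keepdims=True)


def _fit_arrays(
    stack: np.ndarray,
    ridge: float,
    stab_tol: float,
    stab_max_iter: int,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized fit over a (B, N, N, 3) stack of non-degenerate patches.

    Returns (A, C, mean, sigma1, stabilized) with leading batch axis.
    """
    B, N = stack.shape[0], stack.shape[1]
    means = stack.mean(axis=(1, 2))
    Yc = stack - means[:, None, None, :]
    # Mode-3 unfolding, columns in row-major scan order: (B, 3, N^2).
    Y3 = Yc.reshape(B, N * N, 3).transpose(0, 2, 1)
    U3, _, _ = np.linalg.svd(Y3, full_matrices=False)
    C = _fix_signs(U3)
    # Exact identity: states X_(3) = U3^T Y_(3).
    X3 = C.transpose(0, 2, 1) @ Y3
    Xp = _center_columns(X3[:, :, :-1])
    Xn = _center_columns(X3[:, :, 1:])
    if ridge > 0:
        gram = Xp @ Xp.transpose(0, 2, 1) + ridge * np.eye(3)
        cross = Xn @ Xp.transpose(0, 2, 1)
        A = np.linalg.solve(gram, cross.transpose(0, 2, 1)).transpose(0, 2, 1)
    else:
        A = Xn @ np.linalg.pinv(Xp, rcond=PINV_RCOND)
    sigma1 = np.linalg.svd(A, compute_uv=False)[:, 0]
    stabilized = np.zeros(B, dtype=bool)
    for i in np.nonzero(sigma1 > 1.0 + stab_tol)[0]:
        A[i] = stabilize_transition(
            A[i], Xp[i], Xn[i], tol=stab_tol, max_iter=stab_max_iter
        )
        sigma1[i] = largest_singular_value(A[i])
        stabilized[i] = True
    return A, C, means, sigma1, stabilized


def fit_hlds(
    patch: PatchTensor,
    ridge: float = DEFAULT_RIDGE,
    stab_tol: float = DEFAULT_STAB_TOL,
    stab_max_iter: int = DEFAULT_STAB_MAX_ITER,
    degenerate_eps: float = 1e-8,
) -> HLDSModel:
    """Identify the higher-order LDS (A, C) of a single patch."""
    if is_degenerate(patch, eps=degenerate_eps):
        raise DegeneratePatchError(
            f"patch at origin {patch.origin} has no identifiable dynamics"
        )
    A, C, mean, s1, stab = _fit_arrays(
        patch.values[None], ridge, stab_tol, stab_max_iter
    )
    return HLDSModel(
        A=A[0], C=C[0], mean=mean[0],
        stabilized=bool(stab[0]), sigma1=float(s1[0]),
        direction=patch.direction,
    )


def fit_hlds_batch(
    patches: Sequence[PatchTensor],
    ridge: float = DEFAULT_RIDGE,
    stab_tol: float = DEFAULT_STAB_TOL,
    stab_max_iter: int = DEFAULT_STAB_MAX_ITER,
    degenerate_eps: float = 1e-8,
) -> List[HLDSModel]:
    """Fit many patches at once (vectorized; numerically identical to the
    per-patch path).  Degenerate patches must be filtered out beforehand."""
    if not patches:
        return []
    for p in patches:
        if is_degenerate(p, eps=degenerate_eps):
            raise DegeneratePatchError(
                f"degenerate patch at origin {p.origin}; filter before fitting"
            )
    stack = patch_stack(list(patches))
    A, C, mean, s1, stab = _fit_arrays(stack, ridge, stab_tol, stab_max_iter)
    return [
        HLDSModel(A=A[i], C=C[i], mean=mean[i], stabilized=bool(stab[i]),
                  sigma1=float(s1[i]), direction=patches[i].direction)
        for i in range(len(patches))
    ]
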