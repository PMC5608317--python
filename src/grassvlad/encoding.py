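"""Grassmannian codebook learning and VLAD encoding.

The visual vocabulary is a set of k Karcher means on the Grassmann manifold,
initialized by k-medoids on a seeded subsample of the pooled training points
and refined by a few rounds of nearest-word reassignment.  An image's point
cloud is then encoded against the codebook.

Two VLAD variants are shipped because the method's printed form aggregates
*norms* of tangent vectors (a k-dimensional code), while classical VLAD
aggregates the difference *vectors* themselves:

* ``scalar_as_printed`` (default): component i is the sum over points
  assigned to word i of the geodesic distance ||log_map(m_i, G_j)||_F.
* ``tangent_vlad``: block i is the sum of the log-map matrices, flattened
  row-major and concatenated (length k*p*r).

Both are L2-normalized; an all-zero raw vector (empty cloud, or every point
sitting exactly on its word) is returned unnormalized with ``is_zero`` set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .errors import ConfigError, CutLocusError
from .manifold import (
    GrassmannPoint,
    _log_map_batch,
    _stack,
    distance_matrix,
    k_medoids,
    karcher_mean,
    pairwise_distances,
)

VARIANTS = ("scalar_as_printed", "tangent_vlad")

# Noise floor of arccos near 1: a point equal to its word measures ~1e-8,
# not 0.  Residuals below this are treated as exactly zero.
RESIDUAL_EPS = 1e-7


@dataclass
class Codebook:
    """k Grassmannian words (Karcher means) plus training provenance."""

    words: List[GrassmannPoint]
    seed: int = 0
    training_meta: Dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {w.shape for w in self.words}
        if len(shapes) != 1:
            raise ConfigError("all codebook words must share one (p, r) shape")
        W = self.stack()
        if len(self.words) > 1:
            D = pairwise_distances(W, W)
            off = D[~np.eye(len(self.words), dtype=bool)]
            if off.min() < RESIDUAL_EPS:
                raise ConfigError("duplicate codebook words")

    @property
    def k(self) -> int:
        return len(self.words)

    def stack(self) -> np.ndarray:
        return np.stack([w.basis for w in self.words])


@dataclass
class VLADCode:
    """L2-normalized per-image encoding (or a flagged zero code)."""

    values: np.ndarray
    variant: str
    is_zero: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown VLAD variant {self.variant!r}")


def l2_normalize(v: np.ndarray):
    """Return (v / ||v||_2, False), or (v, True) when the norm is zero."""
    v = np.asarray(v, dtype=np.float64)
    norm = np.linalg.norm(v)
    if norm == 0.0:
        return v, True
    return v / norm, False


def _as_stack(points: Union[np.ndarray, Sequence[GrassmannPoint]]) -> np.ndarray:
    arr = _stack(points) if not isinstance(points, np.ndarray) else points
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def assign_points(
    points: Union[np.ndarray, Sequence[GrassmannPoint]], codebook: Codebook
) -> np.ndarray:
    """Nearest-word index for each point (geodesic distance; ties -> lowest
    word index)."""
    P = _as_stack(points)
    D = pairwise_distances(P, codebook.stack())
    return np.argmin(D, axis=1)


def learn_codebook(
    points: Union[np.ndarray, Sequence[GrassmannPoint]],
    k: int,
    seed: int = 0,
    subsample_cap: int = 2000,
    refine_iters: int = 10,
    karcher_tol: float = 1e-6,
    karcher_max_iter: int = 100,
) -> Codebook:
    """Learn k Karcher-mean words from pooled training points.

    Seeded uniform subsample to ``subsample_cap`` points, k-medoids
    initialization on the full pairwise distance matrix, per-cluster Karcher
    means, then up to ``refine_iters`` rounds of {reassign, re-average},
    stopping early once assignments are stable.  An emptied cluster is
    re-seeded to the point farthest from its nearest word.  Deterministic
    given ``seed``.
    """
    P = _as_stack(points)
    n = P.shape[0]
    rng = np.random.default_rng(seed)
    if n > subsample_cap:
        idx = np.sort(rng.choice(n, size=subsample_cap, replace=False))
        P = P[idx]
        n = subsample_cap
    if k > n:
        raise ConfigError(f"k={k} exceeds available points n={n}")
    D = distance_matrix(P)
    medoid_idx = k_medoids(P, k, seed=seed, dist=D)
    assignments = np.argmin(D[:, medoid_idx], axis=1)
    words = []
    for j in range(k):
        members = np.nonzero(assignments == j)[0]
        init = GrassmannPoint(P[medoid_idx[j]])
        if members.size == 0:
            words.append(init)
            continue
        words.append(karcher_mean(
            [GrassmannPoint(P[i]) for i in members],
            init=init, tol=karcher_tol, max_iter=karcher_max_iter,
        ))
    rounds = 0
    reseeded = 0
    for rounds in range(1, refine_iters + 1):
        W = np.stack([w.basis for w in words])
        new_assign = np.argmin(pairwise_distances(P, W), axis=1)
        if np.array_equal(new_assign, assignments):
            break
        assignments = new_assign
        for j in range(k):
            members = np.nonzero(assignments == j)[0]
            if members.size == 0:
                # Re-seed to the point farthest from its nearest word.
                d_near = pairwise_distances(P, W).min(axis=1)
                far = int(np.argmax(d_near))
                words[j] = GrassmannPoint(P[far])
                reseeded += 1
                continue
            words[j] = karcher_mean(
                [GrassmannPoint(P[i]) for i in members],
                init=words[j], tol=karcher_tol, max_iter=karcher_max_iter,
            )
    meta = {
        "n_points_pooled": int(_as_stack(points).shape[0]),
        "n_points_used": int(n),
        "subsample_cap": int(subsample_cap),
        "refine_rounds": int(rounds),
        "clusters_reseeded": int(reseeded),
    }
    return Codebook(words=words, seed=seed, training_meta=meta)


def encode_image(
    points: Union[np.ndarray, Sequence[GrassmannPoint]],
    codebook: Codebook,
    variant: str = "scalar_as_printed",
) -> VLADCode:
    """VLAD code of one image's point cloud against the codebook.

    Sums run in ascending point-index order for floating-point determinism;
    empty clusters contribute zeros and an empty cloud yields a flagged zero
    code.
    """
    if variant not in VARIANTS:
        raise ConfigError(f"unknown VLAD variant {variant!r}")
    k = codebook.k
    p, r = codebook.words[0].shape
    if isinstance(points, np.ndarray):
        P = points if points.ndim == 3 else points[None]
    elif len(points):
        P = np.stack([pt.basis for pt in points])
    else:
        P = np.zeros((0, p, r))
    if P.shape[0] == 0:
        length = k if variant == "scalar_as_printed" else k * p * r
        return VLADCode(np.zeros(length), variant=variant, is_zero=True)
    W = codebook.stack()
    D = pairwise_distances(P, W)
    assign = np.argmin(D, axis=1)
    if variant == "scalar_as_printed":
        D = np.where(D < RESIDUAL_EPS, 0.0, D)
        raw = np.zeros(k)
        for j in range(k):
            members = np.nonzero(assign == j)[0]
            raw[j] = D[members, j].sum()
    else:
        raw = np.zeros((k, p, r))
        for j in range(k):
            members = np.nonzero(assign == j)[0]
            if members.size == 0:
                continue
            try:
                tangents = _log_map_batch(W[j], P[members])
            except CutLocusError:
                # a point exactly orthogonal to its nearest word: skip it
                keep = []
                for i in members:
                    try:
                        keep.append(_log_map_batch(W[j], P[i][None])[0])
                    except CutLocusError:
                        continue
                tangents = np.stack(keep) if keep else np.zeros((0, p, r))
            if tangents.shape[0]:
                norms = np.linalg.norm(tangents, axis=(1, 2))
                tangents[norms < RESIDUAL_EPS] = 0.0
                raw[j] = tangents.sum(axis=0)
        raw = raw.reshape(-1)
    values, is_zero = l2_normalize(raw)
    return VLADCode(values, variant=variant, is_zero=is_zero)
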