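"""Synthetic RGB textures from known linear dynamical systems.

Every pipeline stage is testable without external data: each class of a
synthetic dataset owns a stable system (A, C) whose state recursion
x(i+1) = A x(i) + sigma_v v(i) is run over pixels in row-major scan order and
mapped to RGB as mean + obs_scale * C x(i) + sigma_w w(i), clipped to [0, 1].
Images are mosaics of independently initialized tiles, so tiles are i.i.d.
realizations of the class system — exactly the structure the per-patch
pipeline assumes.  Ground-truth systems are stored in a sidecar JSON the
pipeline never reads.

The observation scale (default 0.05 of the [0, 1] intensity range) keeps the
texture well inside the valid range: with channel means drawn in [0.4, 0.6]
clipping would require an ~8-sigma state excursion, so the noiseless recovery
tests see exactly linear data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .errors import ConfigError, DataError
from .manifold import GrassmannPoint, _orthonormalize, pairwise_distances
from .patches import ImageRecord, PatchTensor


def _random_orthogonal(rng: np.random.Generator, n: int = 3) -> np.ndarray:
    """Haar-ish random orthogonal matrix via sign-fixed QR of a Gaussian."""
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return q * signs


@dataclass
class SyntheticSystemSpec:
    """A known stable generator system: x(t+1)=A x(t)+sigma_v v, pixel =
    mean + obs_scale * C x(t) + sigma_w w."""

    A_true: np.ndarray
    C_true: np.ndarray
    mean: np.ndarray
    sigma_v: float = 0.25
    sigma_w: float = 0.01
    obs_scale: float = 0.05
    seed: int = 0

    def __post_init__(self):
        self.A_true = np.asarray(self.A_true, dtype=np.float64)
        self.C_true = np.asarray(self.C_true, dtype=np.float64)
        self.mean = np.asarray(self.mean, dtype=np.float64)
        if np.max(np.abs(self.C_true.T @ self.C_true - np.eye(3))) > 1e-10:
            raise ConfigError("C_true must be orthogonal")
        if self.sigma_v < 0 or self.sigma_w < 0:
            raise ConfigError("noise levels must be >= 0")

    def observability_point(self, m: int = 3) -> GrassmannPoint:
        A, C = self.A_true, self.C_true
        blocks = [C]
        for _ in range(m - 1):
            blocks.append(blocks[-1] @ A)
        return GrassmannPoint(_orthonormalize(np.vstack(blocks)), m=m)


def make_stable_system(
    seed: int,
    rho: float = 0.97,
    sigma_v: float = 0.25,
    sigma_w: float = 0.01,
    obs_scale: float = 0.05,
) -> SyntheticSystemSpec:
    """Draw a rotation-like transition with sigma_1 = rho * U(0.7, 1), a Haar
    orthogonal mapping matrix, and channel means in [0.4, 0.6]."""
    if not (0 < rho <= 1):
        raise ConfigError("rho must be in (0, 1]")
    rng = np.random.default_rng(seed)
    scale = rho * rng.uniform(0.7, 1.0)
    A = scale * _random_orthogonal(rng)
    C = _random_orthogonal(rng)
    mean = rng.uniform(0.4, 0.6, size=3)
    return SyntheticSystemSpec(
        A_true=A, C_true=C, mean=mean,
        sigma_v=sigma_v, sigma_w=sigma_w, obs_scale=obs_scale, seed=seed,
    )


def synth_patch(
    spec: SyntheticSystemSpec,
    size: int,
    seed: int,
    x0: Optional[np.ndarray] = None,
) -> PatchTensor:
    """Generate one size x size x 3 patch from the system, pixels in row-major
    scan order.  Deterministic given (spec, size, seed)."""
    if size < 4:
        raise ConfigError("patch size must be >= 4")
    rng = np.random.default_rng(seed)
    n = size * size
    x = np.empty((3, n))
    x[:, 0] = rng.standard_normal(3) if x0 is None else np.asarray(x0, float)
    if spec.sigma_v > 0:
        noise = spec.sigma_v * rng.standard_normal((3, n - 1))
        for i in range(n - 1):
            x[:, i + 1] = spec.A_true @ x[:, i] + noise[:, i]
    else:
        for i in range(n - 1):
            x[:, i + 1] = spec.A_true @ x[:, i]
    obs = spec.mean[:, None] + spec.obs_scale * (spec.C_true @ x)
    if spec.sigma_w > 0:
        obs = obs + spec.sigma_w * rng.standard_normal((3, n))
    values = np.clip(obs.T.reshape(size, size, 3), 0.0, 1.0)
    return PatchTensor(values, origin=(0, 0))


def make_class_systems(
    n_classes: int,
    seed: int,
    class_separation: float = 0.8,
    rho: float = 0.97,
    m: int = 3,
    sigma_v: float = 0.25,
    sigma_w: float = 0.01,
    obs_scale: float = 0.05,
    max_tries: int = 500,
) -> Tuple[List[SyntheticSystemSpec], float]:
    """Rejection-sample class systems until all pairwise observability-subspace
    distances reach ``class_separation``; returns (systems, achieved minimum)."""
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        seeds = [int(rng.integers(0, 2**31 - 1)) for _ in range(n_classes)]
        systems = [
            make_stable_system(s, rho=rho, sigma_v=sigma_v,
                               sigma_w=sigma_w, obs_scale=obs_scale)
            for s in seeds
        ]
        pts = np.stack([s.observability_point(m).basis for s in systems])
        D = pairwise_distances(pts, pts)
        off = D[~np.eye(n_classes, dtype=bool)]
        achieved = float(off.min()) if off.size else np.inf
        if n_classes == 1 or achieved >= class_separation:
            return systems, achieved
    raise ConfigError(
        f"could not reach class separation {class_separation} in {max_tries} draws"
    )


@dataclass
class SyntheticDatasetSpec:
    """Study conditions of the synthetic benchmark."""

    n_classes: int = 3
    images_per_class: int = 30
    image_size: int = 128
    patch_size: int = 8          # tile size of the mosaic
    class_separation: float = 0.8
    patients_per_class: int = 7
    sigma_v: float = 0.25
    sigma_w: float = 0.01
    obs_scale: float = 0.05
    rho: float = 0.97
    seed: int = 0

    def __post_init__(self):
        if self.image_size % self.patch_size != 0:
            raise ConfigError(
                f"image_size {self.image_size} not divisible by tile size "
                f"{self.patch_size}"
            )


def synth_image(
    system: SyntheticSystemSpec, image_size: int, tile_size: int, seed: int
) -> np.ndarray:
    """Mosaic of independently seeded tiles from one class system (fresh
    initial state per tile); returns an H x W x 3 float image in [0, 1]."""
    if image_size % tile_size != 0:
        raise ConfigError("image_size must be divisible by tile_size")
    g = image_size // tile_size
    rng = np.random.default_rng(seed)
    img = np.empty((image_size, image_size, 3))
    for r in range(g):
        for c in range(g):
            tile_seed = int(rng.integers(0, 2**31 - 1))
            tile = synth_patch(system, tile_size, tile_seed)
            img[r * tile_size:(r + 1) * tile_size,
                c * tile_size:(c + 1) * tile_size, :] = tile.values
    return img


def make_dataset(spec: SyntheticDatasetSpec, out_dir) -> Path:
    """Write PNG images, a manifest.csv and a ground_truth.json sidecar.

    Fully reproducible from (spec, seed); patient ids are assigned round-robin
    within each class.  Returns the manifest path.
    """
    import imageio.v3 as iio
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    systems, achieved = make_class_systems(
        spec.n_classes, spec.seed, class_separation=spec.class_separation,
        rho=spec.rho, sigma_v=spec.sigma_v, sigma_w=spec.sigma_w,
        obs_scale=spec.obs_scale,
    )
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    for c, system in enumerate(systems):
        label = f"grade{c + 1}"
        for i in range(spec.images_per_class):
            img = synth_image(system, spec.image_size, spec.patch_size,
                              seed=int(rng.integers(0, 2**31 - 1)))
            fname = f"{label}_img{i:03d}.png"
            iio.imwrite(out / fname, np.round(img * 255).astype(np.uint8))
            rows.append({
                "path": fname,
                "label": label,
                "patient_id": f"P{c}_{i % spec.patients_per_class}",
                "magnification": "x40",
            })
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    truth = {
        "achieved_class_separation": achieved,
        "spec": {k: v for k, v in asdict(spec).items()},
        "systems": [
            {"label": f"grade{c + 1}",
             "A": s.A_true.tolist(), "C": s.C_true.tolist(),
             "mean": s.mean.tolist(), "seed": s.seed}
            for c, s in enumerate(systems)
        ],
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return manifest
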