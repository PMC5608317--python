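"""Patch extraction from RGB images.

An image is cut into N x N x 3 tensors (``PatchTensor``) under one of three
sampling strategies — overlapping grid, non-overlapping grid, or random
origins — and each patch is expanded into its four 90-degree clockwise
rotation variants so the spatial signal is modeled along all four scan
directions.  Pixel values are kept in [0, 1]; grid origins are anchored at
(0, 0) and trailing pixels that do not fit a full patch are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .errors import ConfigError, DataError, DimensionError

STRATEGIES = ("overlapping", "non_overlapping", "random")
DIRECTIONS = (0, 90, 180, 270)


@dataclass(frozen=True)
class ImageRecord:
    """One manifest row: an image on disk with its class and patient labels."""

    path: str
    label: str
    patient_id: str
    magnification: Optional[str] = None

    def __post_init__(self):
        if not str(self.label):
            raise DataError(f"empty label for image {self.path!r}")
        if not str(self.patient_id):
            raise DataError(f"empty patient_id for image {self.path!r}")


@dataclass
class PatchTensor:
    """An N x N x 3 tensor in [0,1] cut from an image.

    ``origin`` is the 0-based (row, col) of the top-left pixel in the source
    image; ``direction`` is the clockwise rotation (degrees) applied relative
    to the source orientation.
    """

    values: np.ndarray
    origin: Tuple[int, int]
    direction: int = 0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3 or v.shape[0] != v.shape[1] or v.shape[2] != 3:
            raise DimensionError(f"patch must be N x N x 3, got {v.shape}")
        if v.shape[0] < 4:
            raise DimensionError(
                f"patch side {v.shape[0]} < 4: identification needs more pixels "
                "than the state dimension 3"
            )
        if self.direction not in DIRECTIONS:
            raise ConfigError(f"direction must be one of {DIRECTIONS}")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise DataError("patch values must lie in [0, 1]")
        self.values = v

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass
class PatchingConfig:
    """Sampling strategy for cutting an image into patches."""

    size: int = 8
    strategy: str = "overlapping"
    overlap_fraction: float = 0.5
    n_random: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ConfigError(
                f"strategy must be one of {STRATEGIES}, got {self.strategy!r}"
            )
        if not (0 <= self.overlap_fraction < 1):
            raise ConfigError("overlap_fraction must be in [0, 1)")
        if self.size < 4:
            raise ConfigError("patch size must be >= 4")
        if self.stride < 1:
            raise ConfigError(
                f"stride {self.stride} < 1 (size={self.size}, "
                f"overlap={self.overlap_fraction})"
            )

    @property
    def stride(self) -> int:
        if self.strategy == "non_overlapping":
            return self.size
        return int(round(self.size * (1.0 - self.overlap_fraction)))


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Scale an integer image by its dtype maximum; pass floats through.

    Float inputs are expected to already be in [0, 1].
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DimensionError(f"expected H x W x 3 RGB image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    arr = arr.astype(np.float64)
    if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise DataError("float image values must lie in [0, 1]")
    return arr


def grid_origins(height: int, width: int, size: int, stride: int) -> List[Tuple[int, int]]:
    """All (row, col) origins of fully-contained patches on a regular grid."""
    rows = range(0, height - size + 1, stride)
    cols = range(0, width - size + 1, stride)
    return [(r, c) for r in rows for c in cols]


def extract_patches(image: np.ndarray, cfg: PatchingConfig) -> List[PatchTensor]:
    """Cut an H x W x 3 image (values in [0,1]) into patches per ``cfg``.

    Returns direction-0 patches only; use :func:`rotation_variants` to expand
    them to the four scan directions.  Deterministic given ``cfg`` (the random
    strategy draws origins with replacement from the valid-origin grid using
    ``cfg.seed``).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise DimensionError(f"expected H x W x 3 image, got {img.shape}")
    h, w = img.shape[:2]
    if h < cfg.size or w < cfg.size:
        raise DimensionError(
            f"image {h}x{w} smaller than patch size {cfg.size}"
        )
    if cfg.strategy == "random":
        valid = grid_origins(h, w, cfg.size, 1)
        rng = np.random.default_rng(cfg.seed)
        idx = rng.integers(0, len(valid), size=cfg.n_random)
        origins = [valid[i] for i in idx]
    else:
        origins = grid_origins(h, w, cfg.size, cfg.stride)
    return [
        PatchTensor(img[r : r + cfg.size, c : c + cfg.size, :], origin=(r, c))
        for (r, c) in origins
    ]


def rotation_variants(patch: PatchTensor) -> List[PatchTensor]:
    """The patch plus its 90/180/270-degree clockwise rotations.

    Rotation is applied identically to all three channels; the origin refers
    to the source image and is preserved.
    """
    if patch.direction != 0:
        raise ConfigError("rotation_variants expects a direction-0 patch")
    out = [patch]
    v = patch.values
    for k, direction in enumerate((90, 180, 270), start=1):
        # np.rot90 rotates counter-clockwise for positive k; clockwise is k=-1.
        out.append(
            PatchTensor(np.rot90(v, k=-k, axes=(0, 1)).copy(),
                        origin=patch.origin, direction=direction)
        )
    return out


def is_degenerate(patch: PatchTensor, eps: float = 1e-8) -> bool:
    """True iff the per-channel-mean-subtracted tensor has Frobenius norm < eps*N."""
    if eps <= 0:
        raise ConfigError("eps must be > 0")
    v = patch.values
    centered = v - v.mean(axis=(0, 1), keepdims=True)
    return bool(np.linalg.norm(centered) < eps * patch.size)


def patch_stack(patches: List[PatchTensor]) -> np.ndarray:
    """Stack patch values into a (B, N, N, 3) array for batched fitting."""
    if not patches:
        return np.zeros((0, 4, 4, 3))
    return np.stack([p.values for p in patches], axis=0)
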