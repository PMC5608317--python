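"""End-to-end orchestration: images -> patches -> h-LDS -> Grassmann points
-> per-fold codebook -> VLAD -> SVM -> report.

Per-image point clouds are cached in the working directory, keyed by a content
hash of the stage-prefix configuration (patching, horizon, stabilization), so
re-runs and parameter sweeps over downstream stages (codebook size, VLAD
variant, classifier) reuse the expensive identification stage.

By default the codebook is learned inside each training fold; a shared
codebook learned on all images (the laxer protocol) is available behind a
flag and clearly recorded in the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io as gio
from .encoding import Codebook, encode_image, learn_codebook
from .errors import DataError, GrassVladError
from .evaluation import EvalReport, SplitPlan, evaluate_folds, make_split
from .hlds import fit_hlds_batch
from .manifold import observability_subspaces_batch
from .patches import (
    ImageRecord,
    PatchingConfig,
    extract_patches,
    is_degenerate,
    rotation_variants,
)

logger = logging.getLogger("grassvlad")


@dataclass
class PipelineConfig:
    """Resolved configuration of a full run; round-trips through YAML."""

    manifest: str = "manifest.csv"
    workdir: str = "grassvlad_work"
    # patching
    patch_size: int = 8
    strategy: str = "overlapping"
    overlap_fraction: float = 0.5
    n_random: int = 1000
    # identification
    m: int = 3
    stab_tol: float = 1e-6
    stab_max_iter: int = 50
    degenerate_eps: float = 1e-8
    # codebook / encoding
    k: int = 16
    subsample_cap: int = 2000
    refine_iters: int = 10
    variant: str = "scalar_as_printed"
    shared_codebook: bool = False
    # evaluation
    protocol: str = "kfold"
    n_folds: int = 5
    train_frac: float = 0.7
    n_trials: int = 5
    seed: int = 0

    def patching(self) -> PatchingConfig:
        return PatchingConfig(
            size=self.patch_size, strategy=self.strategy,
            overlap_fraction=self.overlap_fraction,
            n_random=self.n_random, seed=self.seed,
        )

    def stage_prefix_key(self) -> str:
        """Hash of everything that affects per-image point clouds."""
        fields = {
            "patch_size": self.patch_size, "strategy": self.strategy,
            "overlap_fraction": self.overlap_fraction,
            "n_random": self.n_random, "m": self.m,
            "stab_tol": self.stab_tol, "stab_max_iter": self.stab_max_iter,
            "degenerate_eps": self.degenerate_eps, "seed": self.seed,
        }
        return hashlib.sha1(
            json.dumps(fields, sort_keys=True).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise GrassVladError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def image_point_cloud(
    image: np.ndarray, cfg: PipelineConfig
) -> Tuple[np.ndarray, Dict]:
    """All Grassmann points of one image (four directions per kept patch).

    Returns an (n, 3m, 3) basis stack plus per-image counters (patches kept,
    degenerate patches excluded, stabilizations performed).
    """
    patches = extract_patches(image, cfg.patching())
    kept, degenerate = [], 0
    for p in patches:
        if is_degenerate(p, eps=cfg.degenerate_eps):
            degenerate += 1
            continue
        kept.extend(rotation_variants(p))
    if not kept:
        return np.zeros((0, 3 * cfg.m, 3)), {
            "patches": len(patches), "degenerate": degenerate,
            "points": 0, "stabilized": 0,
        }
    models = fit_hlds_batch(
        kept, stab_tol=cfg.stab_tol, stab_max_iter=cfg.stab_max_iter,
        degenerate_eps=cfg.degenerate_eps,
    )
    A = np.stack([m.A for m in models])
    C = np.stack([m.C for m in models])
    bases = observability_subspaces_batch(A, C, m=cfg.m)
    meta = {
        "patches": len(patches),
        "degenerate": degenerate,
        "points": int(bases.shape[0]),
        "stabilized": int(sum(m.stabilized for m in models)),
    }
    return bases, meta


def compute_clouds(
    records: Sequence[ImageRecord], cfg: PipelineConfig
) -> List[np.ndarray]:
    """Point cloud per image, cached under workdir/clouds/<hash>/."""
    cache = Path(cfg.workdir) / "clouds" / cfg.stage_prefix_key()
    cache.mkdir(parents=True, exist_ok=True)
    clouds = []
    hits = 0
    for rec in records:
        key = hashlib.sha1(rec.path.encode()).hexdigest()[:20]
        f = cache / f"{key}.npz"
        if f.exists():
            bases, _ = gio.load_cloud(f)
            hits += 1
        else:
            try:
                image = gio.load_image(rec.path)
                bases, meta = image_point_cloud(image, cfg)
            except GrassVladError as exc:
                raise type(exc)(f"[embed stage] {rec.path}: {exc}") from exc
            gio.save_cloud(f, bases, meta)
        clouds.append(bases)
    logger.info("clouds: %d images, %d cache hits", len(records), hits)
    return clouds


def _fold_codebook(
    clouds: Sequence[np.ndarray], train_idx: np.ndarray, cfg: PipelineConfig,
    fold_seed: int,
) -> Codebook:
    pooled = np.concatenate([clouds[i] for i in train_idx], axis=0)
    if pooled.shape[0] == 0:
        raise DataError("no points available for codebook training")
    return learn_codebook(
        pooled, k=cfg.k, seed=fold_seed,
        subsample_cap=cfg.subsample_cap, refine_iters=cfg.refine_iters,
    )


def run_pipeline(cfg: PipelineConfig) -> EvalReport:
    """Execute the full method and return the evaluation report."""
    records = gio.read_manifest(cfg.manifest)
    for rec in records:
        if not Path(rec.path).exists():
            raise DataError(f"[manifest] image missing: {rec.path}")
    clouds = compute_clouds(records, cfg)
    plan = make_split(
        records, protocol=cfg.protocol, seed=cfg.seed,
        n_folds=cfg.n_folds, train_frac=cfg.train_frac, n_trials=cfg.n_trials,
    )
    labels = [r.label for r in records]
    shared = None
    if cfg.shared_codebook:
        logger.warning("shared codebook mode: vocabulary sees test images")
        shared = _fold_codebook(clouds, np.arange(len(records)), cfg, cfg.seed)
    codes_per_fold = []
    for fold_i, (tr, te) in enumerate(plan.folds):
        if shared is not None:
            book = shared
        else:
            # Leakage guard: vocabulary learned on training images only.
            assert not set(tr) & set(te)
            book = _fold_codebook(clouds, tr, cfg, cfg.seed + 1000 * (fold_i + 1))
        def encode(idx):
            out = []
            for i in idx:
                code = encode_image(clouds[i], book, variant=cfg.variant)
                if code.is_zero:
                    logger.warning("zero code for image %s", records[i].path)
                out.append(code.values)
            return np.stack(out)
        codes_per_fold.append((encode(tr), encode(te)))
        logger.info("fold %d: codebook %s, %d train / %d test codes",
                    fold_i, book.training_meta.get("n_points_used"),
                    len(tr), len(te))
    config_echo = asdict(cfg)
    config_echo["codebook_mode"] = "shared" if cfg.shared_codebook else "per_fold"
    report = evaluate_folds(codes_per_fold, records, plan,
                            seed=cfg.seed, config=config_echo)
    return report
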