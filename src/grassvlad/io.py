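"""Reading and writing pipeline artifacts.

Manifests are CSV with header ``path,label,patient_id,magnification``; images
are PNG/TIFF/JPEG decoded through imageio and scaled to [0, 1] by the dtype
maximum.  Point clouds and codebooks are persisted as .npz containers with
shape metadata; codes as CSV (one row per image); reports as JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .encoding import Codebook, VLADCode
from .errors import DataError
from .manifold import GrassmannPoint
from .patches import ImageRecord, normalize_image

MANIFEST_COLUMNS = ("path", "label", "patient_id")


def read_manifest(path: Union[str, Path]) -> List[ImageRecord]:
    """Parse a manifest CSV into ImageRecords.

    Image paths are resolved relative to the manifest's directory.  Malformed
    rows are reported with their line number; duplicate paths warn but are
    kept; an empty manifest is an error.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"manifest {path} missing columns: {missing}")
    if len(df) == 0:
        raise DataError(f"manifest {path} is empty")
    base = path.parent
    records = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        for col in MANIFEST_COLUMNS:
            if pd.isna(row[col]) or not str(row[col]).strip():
                raise DataError(f"{path}:{line}: empty {col!r}")
        p = Path(str(row["path"]))
        if not p.is_absolute():
            p = base / p
        mag = row.get("magnification")
        records.append(ImageRecord(
            path=str(p), label=str(row["label"]),
            patient_id=str(row["patient_id"]),
            magnification=None if pd.isna(mag) else str(mag),
        ))
    paths = [r.path for r in records]
    dupes = {p for p in paths if paths.count(p) > 1}
    if dupes:
        warnings.warn(f"manifest contains duplicate paths: {sorted(dupes)[:5]}")
    return records


def load_image(path: Union[str, Path]) -> np.ndarray:
    """Decode an RGB image and scale it to [0, 1] floats."""
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise DataError(f"image not found: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DataError(f"{path}: expected an RGB image, got shape {arr.shape}")
    return normalize_image(arr)


# ---------------------------------------------------------------------------
# Point clouds
# ---------------------------------------------------------------------------

def save_cloud(path: Union[str, Path], bases: np.ndarray, meta: dict = None) -> None:
    """Persist an (n, p, r) stack of Grassmann bases with shape metadata."""
    bases = np.asarray(bases)
    np.savez(
        path, bases=bases,
        p=bases.shape[1] if bases.ndim == 3 else 0,
        r=bases.shape[2] if bases.ndim == 3 else 0,
        count=bases.shape[0],
        meta=json.dumps(meta or {}),
    )


def load_cloud(path: Union[str, Path]):
    with np.load(path, allow_pickle=False) as z:
        bases = z["bases"]
        meta = json.loads(str(z["meta"]))
    return bases, meta


# ---------------------------------------------------------------------------
# Codebooks, codes, reports
# ---------------------------------------------------------------------------

def save_codebook(path: Union[str, Path], codebook: Codebook) -> None:
    np.savez(
        path, words=codebook.stack(), seed=codebook.seed,
        meta=json.dumps(codebook.training_meta),
    )


def load_codebook(path: Union[str, Path]) -> Codebook:
    with np.load(path, allow_pickle=False) as z:
        words = [GrassmannPoint(b) for b in z["words"]]
        return Codebook(words=words, seed=int(z["seed"]),
                        training_meta=json.loads(str(z["meta"])))


def write_codes_csv(
    path: Union[str, Path],
    records: Sequence[ImageRecord],
    codes: Sequence[VLADCode],
) -> None:
    """One row per image: path, label, patient_id, zero flag, components."""
    rows = []
    for rec, code in zip(records, codes):
        row = {"path": rec.path, "label": rec.label,
               "patient_id": rec.patient_id, "is_zero": code.is_zero}
        row.update({f"v{i}": v for i, v in enumerate(code.values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_report(report, path: Union[str, Path]) -> None:
    """Emit an EvalReport as JSON plus a sibling .txt summary table and, when
    per-image predictions are present, a .predictions.csv."""
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=1))
    path.with_suffix(".txt").write_text(report.summary() + "\n")
    if report.predictions:
        pd.DataFrame(report.predictions).to_csv(
            path.with_suffix(".predictions.csv"), index=False)


def save_model(path: Union[str, Path], model) -> None:
    import joblib

    joblib.dump(model, path)


def load_model(path: Union[str, Path]):
    import joblib

    return joblib.load(path)
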