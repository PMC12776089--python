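"""Volume and table I/O plus run manifests.

Volumes are NIfTI (single-precision storage by default, affine preserved);
covariate tables are CSV with "" and "NA" as missing tokens; reports are
JSON/CSV. Voxel indices are 0-based throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .tabular import FeatureTable


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D NIfTI volume; returns (data, affine)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:
        raise ValueError(f"{path}: unreadable or truncated NIfTI ({exc})") from exc
    return np.asarray(data), np.asarray(img.affine)


def write_volume(array: np.ndarray, affine: np.ndarray, path: str | Path,
                 dtype=np.float32):
    array = np.asarray(array)
    if array.ndim != 3:
        raise ValueError(f"expected 3D volume, got shape {array.shape}")
    nib.save(nib.Nifti1Image(array.astype(dtype), np.asarray(affine)), str(path))


def read_paired_volumes(path_a, path_b) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a, aff_a = read_volume(path_a)
    b, aff_b = read_volume(path_b)
    if a.shape != b.shape:
        raise ValueError(f"paired volumes differ in shape: {a.shape} vs {b.shape}")
    return a, b, aff_a


def read_covariates(path: str | Path) -> FeatureTable:
    return FeatureTable.from_csv(path)


def write_report(report: dict, path: str | Path):
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_manifest(outdir: str | Path, stage: str, config: dict,
                   inputs: list[str], outputs: list[str]):
    """Record what produced what, so artifacts are regenerable from (config, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entry = {"stage": stage, "config": config, "inputs": inputs, "outputs": outputs}
    mpath = outdir / "manifest.json"
    existing = json.loads(mpath.read_text()) if mpath.exists() else []
    existing.append(entry)
    mpath.write_text(json.dumps(existing, indent=2, default=_json_default))
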