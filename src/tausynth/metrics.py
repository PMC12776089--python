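"""Image-fidelity metrics for synthetic vs true tau-PET volumes.

Regional Pearson correlations across subjects (and their average, Corr_AVG),
voxel-wise MAPE / MAE, windowed SSIM, and voxel-wise Cohen's d effect maps.
MAPE and MAE default to the brain mask (background excluded) so the
percentage error stays defined; a whole-grid mode is available.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .atlas import Atlas


@dataclass
class FidelityReport:
    """Per-ROI and global agreement between synthetic and true volumes."""

    per_roi_pearson: dict[int, float]
    corr_avg: float
    mape_percent: float
    mae: float
    ssim: float
    n_subjects: int
    per_roi_mape: dict[int, float] = field(default_factory=dict)
    per_roi_mae: dict[int, float] = field(default_factory=dict)

    def save(self, out_prefix: str | Path):
        out_prefix = Path(out_prefix)
        rows = [{"roi_id": rid, "pearson_r": r,
                 "mape_percent": self.per_roi_mape.get(rid, np.nan),
                 "mae": self.per_roi_mae.get(rid, np.nan)}
                for rid, r in self.per_roi_pearson.items()]
        pd.DataFrame(rows).to_csv(out_prefix.with_suffix(".csv"), index=False)
        glob = {"corr_avg": self.corr_avg, "mape_percent": self.mape_percent,
                "mae": self.mae, "ssim": self.ssim, "n_subjects": self.n_subjects}
        out_prefix.with_suffix(".json").write_text(json.dumps(glob, indent=2))


def roi_pearson(pred_suvr: np.ndarray, true_suvr: np.ndarray,
                roi_ids: list[int] | None = None) -> tuple[dict[int, float], float]:
    """Across-subject Pearson r per ROI column, and their mean (Corr_AVG).

    Zero-variance columns yield an undefined correlation; these are reported
    as NaN with a warning and excluded from the average.
    """
    pred = np.asarray(pred_suvr, dtype=float)
    true = np.asarray(true_suvr, dtype=float)
    if pred.shape != true.shape or pred.ndim != 2:
        raise ValueError("pred and true must be matched subjects x ROIs matrices")
    if pred.shape[0] < 3:
        raise ValueError("need at least 3 subjects for regional correlations")
    ids = roi_ids if roi_ids is not None else list(range(pred.shape[1]))
    out: dict[int, float] = {}
    for j, rid in enumerate(ids):
        x, y = pred[:, j], true[:, j]
        sx, sy = x.std(), y.std()
        if sx == 0.0 or sy == 0.0:
            warnings.warn(f"ROI {rid}: zero variance, correlation undefined")
            out[rid] = np.nan
            continue
        out[rid] = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    vals = [v for v in out.values() if not np.isnan(v)]
    corr_avg = float(np.mean(vals)) if vals else np.nan
    return out, corr_avg


def _masked(pred, true, mask):
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("volume shapes differ")
    if mask is None:
        return pred.ravel(), true.ravel()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != true.shape:
        raise ValueError("mask shape differs from volumes")
    return pred[mask], true[mask]


def mape(pred: np.ndarray, true: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean absolute percentage error, 100 * mean(|pred-true| / true)."""
    p, t = _masked(pred, true, mask)
    n_bad = int((t <= 0).sum())
    if n_bad:
        raise ValueError(f"MAPE undefined: {n_bad} non-positive true voxels in domain")
    return float(100.0 * np.mean(np.abs(p - t) / t))


def mae(pred: np.ndarray, true: np.ndarray, mask: np.ndarray | None = None) -> float:
    p, t = _masked(pred, true, mask)
    return float(np.mean(np.abs(p - t)))


def ssim(pred: np.ndarray, true: np.ndarray, win_size: int = 7,
         data_range: float | None = None, gaussian: bool = False) -> float:
    """Windowed structural similarity (luminance * contrast * structure).

    Uniform 7^3 window by default with the canonical stabilizing constants;
    dynamic range inferred from the true volume unless supplied.
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("volume shapes differ")
    if any(win_size > s for s in true.shape):
        raise ValueError(f"window {win_size} exceeds volume shape {true.shape}")
    if data_range is None:
        data_range = float(true.max() - true.min())
        if data_range == 0.0:
            data_range = max(float(np.abs(true).max()), 1.0)
    return float(structural_similarity(
        true, pred, win_size=win_size, data_range=data_range,
        gaussian_weights=gaussian))


def cohens_d_map(group_a: np.ndarray, group_b: np.ndarray) -> np.ndarray:
    """Voxel-wise Cohen's d, (mean_a - mean_b) / pooled SD (df = n_a + n_b - 2).

    Voxels with zero pooled SD are set to 0 (a count is warned).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 volumes per group")
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ssa = ((a - ma) ** 2).sum(axis=0)
    ssb = ((b - mb) ** 2).sum(axis=0)
    pooled = np.sqrt((ssa + ssb) / (na + nb - 2))
    zero = pooled == 0
    nz = int(zero.sum())
    if nz:
        warnings.warn(f"Cohen's d: {nz} voxels with zero pooled SD set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(zero, 0.0, (ma - mb) / np.where(zero, 1.0, pooled))
    return d


def evaluate_volumes(pred_vols: list[np.ndarray], true_vols: list[np.ndarray],
                     atlas: Atlas, masked: bool = True) -> FidelityReport:
    """Full fidelity report over paired subject volumes."""
    from .atlas import regional_suvr

    if len(pred_vols) != len(true_vols) or not pred_vols:
        raise ValueError("need equal non-empty prediction/truth lists")
    ids = atlas.roi_ids
    pred_mat = np.array([[regional_suvr(v, atlas)[r] for r in ids] for v in pred_vols])
    true_mat = np.array([[regional_suvr(v, atlas)[r] for r in ids] for v in true_vols])
    per_roi, corr_avg = roi_pearson(pred_mat, true_mat, ids)

    mask = atlas.brain_mask if masked else None
    mapes = [mape(p, t, mask) for p, t in zip(pred_vols, true_vols)]
    maes = [mae(p, t, mask) for p, t in zip(pred_vols, true_vols)]
    ssims = [ssim(p, t) for p, t in zip(pred_vols, true_vols)]

    lab = atlas.label_volume
    per_mape = {r: float(np.mean([mape(p, t, lab == r) for p, t in zip(pred_vols, true_vols)]))
                for r in ids}
    per_mae = {r: float(np.mean([mae(p, t, lab == r) for p, t in zip(pred_vols, true_vols)]))
               for r in ids}
    return FidelityReport(per_roi, corr_avg, float(np.mean(mapes)), float(np.mean(maes)),
                          float(np.mean(ssims)), len(pred_vols), per_mape, per_mae)
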