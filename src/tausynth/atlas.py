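"""ROI atlas: a Desikan-Killiany-style integer parcellation abstraction.

The synthetic atlas is a Voronoi parcellation inside an ellipsoidal brain
mask with hemisphere-paired regions, each carrying the Braak stage at which
tau first appears there, and a temporal meta-ROI composite. Real label
volumes (e.g. FreeSurfer-derived) can be loaded through the same type as
long as an ROI table is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

ROI_TABLE_COLUMNS = ["id", "name", "hemisphere", "lobe", "braak_onset_stage", "in_meta_temp"]


@dataclass
class Atlas:
    """Integer label volume (0 = background) plus per-ROI metadata."""

    label_volume: np.ndarray
    roi_table: pd.DataFrame
    meta_temp_members: frozenset[int]
    grid: tuple[int, int, int]

    def __post_init__(self):
        self.label_volume = np.asarray(self.label_volume)
        self.grid = tuple(self.grid)
        self.validate()

    # cached voxel counts per ROI id
    @property
    def roi_sizes(self) -> dict[int, int]:
        if not hasattr(self, "_sizes"):
            labels, counts = np.unique(self.label_volume, return_counts=True)
            self._sizes = {int(l): int(c) for l, c in zip(labels, counts) if l != 0}
        return self._sizes

    @property
    def roi_ids(self) -> list[int]:
        return [int(i) for i in self.roi_table["id"]]

    @property
    def brain_mask(self) -> np.ndarray:
        return self.label_volume > 0

    def validate(self):
        if self.label_volume.shape != self.grid:
            raise ValueError(f"label volume shape {self.label_volume.shape} != grid {self.grid}")
        ids = set(self.roi_ids)
        present = set(int(v) for v in np.unique(self.label_volume)) - {0}
        if not present <= ids:
            raise ValueError(f"labels without a roi_table entry: {sorted(present - ids)}")
        empty = ids - present
        if empty:
            raise ValueError(f"ROIs with zero voxels: {sorted(empty)}")
        if not set(self.meta_temp_members) <= ids:
            raise ValueError("meta_temp_members contains unknown ROI ids")

    # ------------------------------------------------------------------ I/O
    def save(self, label_path: str | Path, table_path: str | Path):
        nib.save(nib.Nifti1Image(self.label_volume.astype(np.int16), np.eye(4)), str(label_path))
        tab = self.roi_table.copy()
        tab["in_meta_temp"] = [int(i in self.meta_temp_members) for i in tab["id"]]
        tab[ROI_TABLE_COLUMNS].to_csv(table_path, index=False)

    @classmethod
    def load(cls, label_path: str | Path, table_path: str | Path) -> "Atlas":
        img = nib.load(str(label_path))
        vol = np.asarray(img.dataobj).astype(np.int32)
        tab = pd.read_csv(table_path)
        missing = set(ROI_TABLE_COLUMNS) - set(tab.columns)
        if missing:
            raise ValueError(f"roi_table missing columns: {sorted(missing)}")
        members = frozenset(int(i) for i, m in zip(tab["id"], tab["in_meta_temp"]) if m)
        return cls(vol, tab, members, vol.shape)


def build_atlas(grid: tuple[int, int, int], n_rois: int, seed: int) -> Atlas:
    """Construct a synthetic hemisphere-paired parcellation.

    ROI seed points are drawn in the left half of an ellipsoidal brain mask
    and mirrored to the right; every mask voxel is assigned to its nearest
    seed. Braak onset stages follow distance from a medial-temporal anchor:
    the closest third of ROI pairs onset at stages 1-2 (medial temporal), the
    middle third at 3-4 (temporal), the rest at 5-6 (neocortical). The
    temporal meta-ROI collects all stage 1-4 regions.
    """
    grid = tuple(int(g) for g in grid)
    if n_rois % 2 != 0 or n_rois < 2:
        raise ValueError("n_rois must be even (hemisphere pairing)")
    if any(g < 8 for g in grid):
        raise ValueError(f"grid dims must be >= 8, got {grid}")

    rng = np.random.default_rng(seed)
    p1, p2, p3 = grid
    center = np.array([(p1 - 1) / 2, (p2 - 1) / 2, (p3 - 1) / 2])
    semi = np.array([0.42 * p1, 0.45 * p2, 0.42 * p3])

    idx = np.indices(grid).reshape(3, -1).T.astype(float)
    mask_flat = (((idx - center) / semi) ** 2).sum(axis=1) <= 1.0
    coords = idx[mask_flat]

    half = n_rois // 2
    left = coords[coords[:, 0] < center[0]]
    if len(left) < half:
        raise ValueError(f"grid {grid} too small to host {n_rois} non-empty ROIs")
    seeds_left = left[rng.choice(len(left), size=half, replace=False)]
    seeds_right = seeds_left.copy()
    seeds_right[:, 0] = 2 * center[0] - seeds_right[:, 0]
    seeds = np.vstack([seeds_left, seeds_right])

    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1) + 1  # labels 1..n_rois

    labels = np.zeros(grid, dtype=np.int32)
    labels[tuple(coords.astype(int).T)] = assign

    counts = np.bincount(assign, minlength=n_rois + 1)[1:]
    if (counts == 0).any():
        raise ValueError(f"grid {grid} too small to host {n_rois} non-empty ROIs")

    # medial-temporal anchor: inferior, near midline
    anchor = np.array([center[0], center[1], center[2] - 0.3 * p3])
    order = np.argsort(((seeds_left - anchor) ** 2).sum(axis=1), kind="stable")

    stages_left = np.zeros(half, dtype=int)
    lobes_left = [""] * half
    third = max(half // 3, 1)
    for rank, j in enumerate(order):
        if rank < third:
            stages_left[j] = 1 + (rank % 2)
            lobes_left[j] = "medial_temporal"
        elif rank < 2 * third:
            stages_left[j] = 3 + (rank % 2)
            lobes_left[j] = "temporal"
        else:
            stages_left[j] = 5 + (rank % 2)
            lobes_left[j] = "neocortical"

    rows = []
    for j in range(half):
        for hemi, rid in (("left", j + 1), ("right", j + 1 + half)):
            rows.append({
                "id": rid,
                "name": f"{lobes_left[j]}_{j + 1:02d}",
                "hemisphere": hemi,
                "lobe": lobes_left[j],
                "braak_onset_stage": int(stages_left[j]),
                "in_meta_temp": int(stages_left[j] <= 4),
            })
    table = pd.DataFrame(rows).sort_values("id").reset_index(drop=True)
    members = frozenset(int(r["id"]) for _, r in table.iterrows() if r["in_meta_temp"])
    return Atlas(labels, table, members, grid)


def regional_suvr(volume: np.ndarray, atlas: Atlas) -> dict[int, float]:
    """Arithmetic mean of voxel values within each ROI (background excluded)."""
    volume = np.asarray(volume)
    if volume.shape != atlas.grid:
        raise ValueError(f"volume shape {volume.shape} does not match atlas grid {atlas.grid}")
    lab = atlas.label_volume.ravel()
    vals = volume.ravel().astype(np.float64)
    sums = np.bincount(lab, weights=vals)
    counts = np.bincount(lab)
    return {rid: float(sums[rid] / counts[rid]) for rid in atlas.roi_ids}


def meta_temp_tau(regional_means: dict[int, float], atlas: Atlas) -> float:
    """Voxel-count-weighted average SUVR over the temporal meta-ROI members.

    Equivalent to the mean SUVR over the union mask of the member regions.
    """
    missing = [r for r in atlas.meta_temp_members if r not in regional_means]
    if missing:
        raise ValueError(f"regional_means missing meta-ROI members: {sorted(missing)}")
    sizes = atlas.roi_sizes
    w = np.array([sizes[r] for r in sorted(atlas.meta_temp_members)], dtype=float)
    m = np.array([regional_means[r] for r in sorted(atlas.meta_temp_members)], dtype=float)
    return float((w * m).sum() / w.sum())
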