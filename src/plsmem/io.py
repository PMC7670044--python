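"""NIfTI and TSV I/O for grids, maps, and condition-image sets."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import VoxelGrid
from .imagesim import ConditionImageSet


def save_map(values: np.ndarray, grid: VoxelGrid, path) -> None:
    """Write a flat per-voxel map as a 3-D NIfTI-1 image."""
    vol = np.asarray(values, dtype=np.float64).reshape(grid.shape)
    nib.save(nib.Nifti1Image(vol, grid.affine), str(path))


def load_map(path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a 3-D NIfTI-1 map back as (flat values, grid)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    grid = VoxelGrid(shape=tuple(int(s) for s in data.shape),
                     affine=np.asarray(img.affine))
    return data.ravel(), grid


def save_condition_images(images: ConditionImageSet, out_dir) -> Path:
    """One 3-D NIfTI per subject x condition, plus an index TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for si, subj in enumerate(images.subjects):
        for ci, cond in enumerate(images.conditions):
            safe = cond.replace(":", "_").replace("/", "_")
            fname = f"sub-{subj:02d}_cond-{safe}.nii"
            save_map(images.values[si, ci], images.grid, out_dir / fname)
            rows.append((subj, cond, fname))
    index = pd.DataFrame(rows, columns=["subject", "condition", "file"])
    index_path = out_dir / "index.tsv"
    index.to_csv(index_path, sep="\t", index=False)
    return index_path


def load_condition_images(index_path) -> ConditionImageSet:
    """Rebuild a ConditionImageSet from an index TSV written above."""
    index_path = Path(index_path)
    index = pd.read_csv(index_path, sep="\t")
    subjects = tuple(sorted(index["subject"].unique()))
    conditions = tuple(index["condition"].unique())
    grid = None
    values = None
    for row in index.itertuples():
        flat, g = load_map(index_path.parent / row.file)
        if grid is None:
            grid = g
            values = np.empty((len(subjects), len(conditions), g.n_voxels))
        values[subjects.index(row.subject),
               conditions.index(row.condition)] = flat
    return ConditionImageSet(values=values, conditions=conditions,
                             grid=grid, subjects=subjects)
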