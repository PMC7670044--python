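"""Seed (functional-connectivity) PLS.

Seed activity is extracted from a small neighborhood around a voxel of
interest (by default the seed voxel plus its adjacent voxels in every
direction, i.e. up to 27 voxels), one scalar per subject and condition.
Seed values are correlated with every voxel across subjects within each
condition, the per-condition correlation maps are stacked into a k x V
matrix, and that matrix is decomposed by SVD with the same conventions as
task PLS. The resulting LVs capture condition-dependent functional
connectivity of the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import VoxelGrid
from .imagesim import ConditionImageSet, cube_indices
from .taskpls import LatentVariable, pls_svd


@dataclass(frozen=True)
class SeedSpec:
    """A seed region: mm center plus a cubic neighborhood radius in voxels."""

    center_mm: tuple[float, float, float]
    neighborhood_voxels: int = 1
    label: str = "seed"


@dataclass(frozen=True)
class SeedActivity:
    """One scalar of seed activity per subject x condition."""

    values: np.ndarray            # (n_subjects, k)
    conditions: tuple[str, ...]
    subjects: tuple[int, ...]
    provenance: str               # "betas" | "timeseries"


def seed_indices(grid: VoxelGrid, spec: SeedSpec) -> np.ndarray:
    """Flat voxel indices of the seed neighborhood, clipped at the edges."""
    return cube_indices(grid, spec.center_mm, spec.neighborhood_voxels)


def extract_seed_values(images: ConditionImageSet,
                        spec: SeedSpec) -> SeedActivity:
    """Seed activity from condition betas: mean over the neighborhood cube."""
    idx = seed_indices(images.grid, spec)
    vals = images.values[:, :, idx].mean(axis=2)
    return SeedActivity(values=vals, conditions=images.conditions,
                        subjects=images.subjects, provenance="betas")


def extract_seed_values_timeseries(
    window_bold: np.ndarray,
    grid: VoxelGrid,
    spec: SeedSpec,
    peak_timepoints: tuple[int, ...] = (2, 3, 4),
) -> np.ndarray:
    """Seed activity from trial-locked BOLD windows.

    ``window_bold`` is (subjects, conditions, timepoints, voxels): the BOLD
    values across an 8-timepoint window from trial onset, already averaged
    over a condition's events. The seed value averages the neighborhood cube
    over the peak and adjacent timepoints (default TRs 2-4, i.e. 4-8 s
    post-onset for a 2 s TR, around the canonical response peak). Returns
    (subjects, conditions).
    """
    if window_bold.ndim != 4:
        raise ValueError("expected (subjects, conditions, time, voxels)")
    n_t = window_bold.shape[2]
    pts = [t for t in peak_timepoints if 0 <= t < n_t]
    if not pts:
        raise ValueError("no peak timepoints inside the window")
    idx = seed_indices(grid, spec)
    return window_bold[:, :, pts][..., idx].mean(axis=(2, 3))


def seed_correlation_maps(
    seed: SeedActivity,
    images: ConditionImageSet,
    conditions: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Cross-subject Pearson correlation of seed activity with every voxel.

    Returns a (k, V) matrix, one correlation map per condition. Voxels (or
    conditions) with zero variance across subjects get r = 0 with a
    warning.
    """
    if conditions is None:
        conditions = images.conditions
    if images.n_subjects < 3:
        raise ValueError("need at least 3 subjects for correlation maps")
    maps = np.zeros((len(conditions), images.grid.n_voxels))
    n_degenerate = 0
    for row, cond in enumerate(conditions):
        ci = images.condition_index(cond)
        si = seed.conditions.index(cond)
        s = seed.values[:, si]
        Y = images.values[:, ci, :]
        s_c = s - s.mean()
        Y_c = Y - Y.mean(axis=0, keepdims=True)
        s_norm = np.linalg.norm(s_c)
        y_norm = np.linalg.norm(Y_c, axis=0)
        ok = (s_norm > 0) & (y_norm > 0)
        n_degenerate += int(np.sum(~ok))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Y_c.T @ s_c) / (y_norm * s_norm)
        maps[row] = np.where(ok, r, 0.0)
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} zero-variance seed/voxel pairs set to r = 0",
            RuntimeWarning, stacklevel=2)
    return np.clip(maps, -1.0, 1.0)


def seed_pls_svd(cm: np.ndarray) -> list[LatentVariable]:
    """SVD of the stacked correlation matrix, task-PLS conventions."""
    return pls_svd(cm)


def seed_pls(images: ConditionImageSet, spec: SeedSpec,
             conditions: tuple[str, ...] | None = None) -> list[LatentVariable]:
    """Full seed PLS from condition betas."""
    seed = extract_seed_values(images, spec)
    return seed_pls_svd(seed_correlation_maps(seed, images, conditions))
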