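"""Mean-centered task PLS.

Stacks all subjects' condition images into one matrix, centers the
condition means about the grand mean, and decomposes the centered
condition-mean matrix by SVD. Each latent variable (LV) pairs a singular
image of voxel saliences with a singular profile of task saliences and a
singular value measuring the covariance it accounts for; brain scores
project each subject-condition image onto an LV's singular image.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .imagesim import ConditionImageSet


@dataclass(frozen=True)
class DataMatrix:
    """Stacked data: rows are (condition, subject) pairs, columns voxels.

    Rows are condition-block ordered: all subjects of condition 0, then all
    subjects of condition 1, and so on; ``row_index(c, s)`` maps back.
    """

    X: np.ndarray                     # (k * n, V)
    conditions: tuple[str, ...]
    subjects: tuple[int, ...]
    grid: object = None

    @property
    def k(self) -> int:
        return len(self.conditions)

    @property
    def n(self) -> int:
        return len(self.subjects)

    def row_index(self, condition: int, subject: int) -> int:
        return condition * self.n + subject

    def row_identity(self, row: int) -> tuple[int, int]:
        return divmod(row, self.n)    # (condition, subject)


def build_datamat(images: ConditionImageSet) -> DataMatrix:
    """Stack a ConditionImageSet into the (k n) x V analysis matrix."""
    n, k, V = images.values.shape
    X = np.transpose(images.values, (1, 0, 2)).reshape(k * n, V)
    return DataMatrix(X=X, conditions=images.conditions,
                      subjects=images.subjects, grid=images.grid)


def mean_center(dm: DataMatrix) -> np.ndarray:
    """Centered condition-mean matrix M (k x V).

    Row c is the mean image of condition c minus the grand mean over all
    conditions, so columns of M sum to zero: the within-subject offsets
    shared across conditions cancel exactly.
    """
    means = dm.X.reshape(dm.k, dm.n, -1).mean(axis=1)
    return means - means.mean(axis=0, keepdims=True)


@dataclass(frozen=True)
class LatentVariable:
    """One LV of a task or seed PLS decomposition."""

    index: int
    singular_value: float
    task_saliences: np.ndarray    # (k,), unit norm
    voxel_saliences: np.ndarray   # (V,), unit norm ("singular image")
    brain_scores: np.ndarray | None = None   # (n, k)
    perm_p: float | None = None

    @property
    def weighted_saliences(self) -> np.ndarray:
        """Voxel saliences scaled by the singular value."""
        return self.singular_value * self.voxel_saliences


def pls_svd(M: np.ndarray, tol: float = 1e-12) -> list[LatentVariable]:
    """SVD of a k x V (centered condition-mean or correlation) matrix.

    Returns LVs ordered by decreasing singular value, dropping numerically
    zero ones (relative tolerance ``tol``). A deterministic sign convention
    is applied: each LV is flipped so its largest-|salience| voxel is
    positive (ties broken by the lowest voxel index).
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite values in the decomposition matrix")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    keep = s > (s[0] * tol if s.size and s[0] > 0 else tol)
    lvs = []
    for l in np.flatnonzero(keep):
        u_task, u_vox = U[:, l].copy(), Vt[l].copy()
        top = np.argmax(np.abs(u_vox))
        if u_vox[top] < 0:
            u_vox, u_task = -u_vox, -u_task
        lvs.append(LatentVariable(
            index=len(lvs), singular_value=float(s[l]),
            task_saliences=u_task, voxel_saliences=u_vox,
        ))
    return lvs


def compute_brain_scores(dm: DataMatrix, lv: LatentVariable) -> np.ndarray:
    """Brain scores: each subject-condition image projected onto the LV.

    Returns an (n, k) array, ``scores[s, c] = X[c, s, :] . u``.
    """
    if dm.X.shape[1] != lv.voxel_saliences.size:
        raise ValueError("voxel dimension mismatch")
    proj = dm.X @ lv.voxel_saliences             # (k * n,)
    return proj.reshape(dm.k, dm.n).T


def task_pls(images: ConditionImageSet) -> list[LatentVariable]:
    """Full mean-centered task PLS: stack, center, decompose, score."""
    dm = build_datamat(images)
    lvs = pls_svd(mean_center(dm))
    return [replace(lv, brain_scores=compute_brain_scores(dm, lv))
            for lv in lvs]
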