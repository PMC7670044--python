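"""Permutation and bootstrap inference for task and seed PLS.

Significance of each latent variable is assessed by permutation: condition
labels are shuffled (within subject by default) and the decomposition is
recomputed, building a null distribution of singular values. Reliability of
voxel saliences is assessed by bootstrap: subjects are resampled with
replacement, the analysis is recomputed, replicates are rotated back onto
the original LVs (Procrustes alignment, which absorbs sign and axis
indeterminacy), and each voxel's bootstrap ratio (BSR) is its original
weighted salience divided by the bootstrap standard error. BSR behaves
approximately like a z score and is thresholded at 3 by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .imagesim import ConditionImageSet
from .taskpls import LatentVariable, build_datamat, mean_center

log = logging.getLogger(__name__)

MatrixFn = Callable[[ConditionImageSet], np.ndarray]


@dataclass(frozen=True)
class ResamplingConfig:
    """Resampling parameters; defaults follow standard PLS practice."""

    n_perm: int = 500
    n_boot: int = 100
    alpha: float = 0.05
    bsr_threshold: float = 3.0
    rng_seed: int = 0
    permutation_unit: str = "within_subject"   # | "unrestricted"
    perm_comparison: str = "rank"              # | "any"

    def __post_init__(self) -> None:
        if self.n_perm < 1 or self.n_boot < 1:
            raise ValueError("n_perm and n_boot must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.bsr_threshold <= 0:
            raise ValueError("bsr_threshold must be > 0")


def task_matrix(images: ConditionImageSet) -> np.ndarray:
    """The centered condition-mean matrix entering task PLS."""
    return mean_center(build_datamat(images))


def _permuted(images: ConditionImageSet,
              rng: np.random.Generator, unit: str) -> ConditionImageSet:
    n, k, V = images.values.shape
    if unit == "within_subject":
        vals = np.empty_like(images.values)
        for s in range(n):
            vals[s] = images.values[s, rng.permutation(k), :]
    elif unit == "unrestricted":
        flat = images.values.reshape(n * k, V)
        vals = flat[rng.permutation(n * k)].reshape(n, k, V)
    else:
        raise ValueError(f"unknown permutation unit {unit!r}")
    return replace(images, values=vals)


def permutation_test(
    images: ConditionImageSet,
    matrix_fn: MatrixFn,
    cfg: ResamplingConfig,
) -> np.ndarray:
    """Permutation p value per LV.

    Condition labels are permuted (within each subject by default, subjects
    being the exchangeable blocks), the matrix and its SVD recomputed, and
    the singular value at each rank compared with the observed one at the
    same rank. p = (exceedances + 1) / (n_perm + 1), so the smallest
    attainable p is 1 / (n_perm + 1). ``perm_comparison="any"`` instead
    counts permutations whose largest singular value exceeds the observed
    one at each rank (the more conservative whole-spectrum comparison).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    s_obs = np.linalg.svd(matrix_fn(images), compute_uv=False)
    count = np.zeros_like(s_obs)
    for _ in range(cfg.n_perm):
        s_perm = np.linalg.svd(
            matrix_fn(_permuted(images, rng, cfg.permutation_unit)),
            compute_uv=False)
        if cfg.perm_comparison == "rank":
            m = min(s_perm.size, s_obs.size)
            count[:m] += s_perm[:m] >= s_obs[:m]
        elif cfg.perm_comparison == "any":
            count += s_perm.max() >= s_obs
        else:
            raise ValueError(
                f"unknown perm_comparison {cfg.perm_comparison!r}")
    return (count + 1.0) / (cfg.n_perm + 1.0)


@dataclass(frozen=True)
class ReliabilityMap:
    """Bootstrap reliability of one LV's voxel saliences."""

    lv_index: int
    salience: np.ndarray          # weighted saliences (singular value * u)
    se: np.ndarray                # bootstrap standard error per voxel
    bsr: np.ndarray               # salience / se
    threshold: float = 3.0

    def mask(self, threshold: float | None = None) -> np.ndarray:
        thr = self.threshold if threshold is None else threshold
        return np.abs(self.bsr) > thr


def _resample_subjects(n: int, rng: np.random.Generator,
                       max_redraws: int = 100) -> np.ndarray:
    for _ in range(max_redraws):
        idx = rng.integers(0, n, size=n)
        if np.unique(idx).size > 1:
            return idx
        log.info("degenerate bootstrap resample (single subject); redrawn")
    raise RuntimeError("could not draw a non-degenerate bootstrap sample")


def bootstrap_reliability(
    images: ConditionImageSet,
    matrix_fn: MatrixFn,
    cfg: ResamplingConfig,
    lvs: list[LatentVariable] | None = None,
) -> list[ReliabilityMap]:
    """Bootstrap standard errors and BSR maps for each LV.

    Subjects are resampled with replacement ``n_boot`` times and the full
    analysis (including, for seed PLS, the cross-subject correlation
    maps) is recomputed on each replicate. Replicate saliences are aligned
    to the original decomposition by orthogonal Procrustes rotation of the
    task-salience space before the per-voxel standard error is taken.
    Voxels with zero bootstrap SE get a +/- inf BSR sentinel (they are
    trivially "reliable") and are counted in the log.
    """
    if images.n_subjects < 3:
        raise ValueError("need at least 3 subjects to bootstrap")
    rng = np.random.default_rng(cfg.rng_seed + 1)
    M = matrix_fn(images)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if lvs is not None:
        L = len(lvs)
    else:
        L = int(np.sum(s > (s[0] * 1e-12 if s.size and s[0] > 0 else 0)))
    U, s, Vt = U[:, :L], s[:L], Vt[:L]
    W_orig = Vt.T * s                                     # (V, L)

    boots = np.empty((cfg.n_boot, Vt.shape[1], L))
    for b in range(cfg.n_boot):
        idx = _resample_subjects(images.n_subjects, rng)
        boot_imgs = replace(
            images,
            values=images.values[idx],
            subjects=tuple(int(images.subjects[i]) for i in idx),
        )
        Ub, sb, Vtb = np.linalg.svd(matrix_fn(boot_imgs),
                                    full_matrices=False)
        Ub, sb, Vtb = Ub[:, :L], sb[:L], Vtb[:L]
        # rotate the replicate onto the original task-salience space
        P, _, Qt = np.linalg.svd(Ub.T @ U, full_matrices=False)
        R = P @ Qt
        boots[b] = (Vtb.T * sb) @ R

    se = boots.std(axis=0, ddof=1)                        # (V, L)
    out = []
    for l in range(L):
        with np.errstate(divide="ignore", invalid="ignore"):
            bsr = W_orig[:, l] / se[:, l]
        zero_se = se[:, l] == 0
        if np.any(zero_se):
            log.info("%d zero-SE voxels on LV %d set to inf BSR",
                     int(zero_se.sum()), l)
            bsr = np.where(zero_se,
                           np.sign(W_orig[:, l]) * np.inf, bsr)
            bsr = np.where(zero_se & (W_orig[:, l] == 0), 0.0, bsr)
        out.append(ReliabilityMap(
            lv_index=l, salience=W_orig[:, l], se=se[:, l],
            bsr=bsr, threshold=cfg.bsr_threshold,
        ))
    return out


def threshold_bsr(rel: ReliabilityMap,
                  threshold: float | None = None) -> dict:
    """Signed reliable-voxel masks at |BSR| > threshold."""
    thr = rel.threshold if threshold is None else threshold
    mask = np.abs(rel.bsr) > thr
    return {
        "mask": mask,
        "positive": mask & (rel.bsr > 0),
        "negative": mask & (rel.bsr < 0),
        "threshold": thr,
    }
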