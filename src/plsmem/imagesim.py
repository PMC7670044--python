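"""Synthetic condition-level activation images with planted ground truth.

Generates a subjects x conditions x voxels array standing in for per-subject
GLM beta images of the six modeled trial types. The generative model plants

* latent task patterns: rank-1 terms ``amplitude * v[c] * u`` with a
  unit-norm task profile v over conditions and a unit-norm spatial map u
  (a Gaussian blob on the grid), the ground truth that mean-centered task
  PLS should recover;
* seed couplings: a per-(subject, condition) latent factor added to a seed
  neighborhood and to a distal coupled voxel set, inducing a known
  cross-subject seed-voxel correlation per condition, the ground truth for
  seed PLS;
* additive subject offsets (voxelwise, shared across conditions, removed by
  mean-centering) and i.i.d. Gaussian noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .design import MODELED_CONDITIONS
from .grid import VoxelGrid


@dataclass(frozen=True)
class ConditionImageSet:
    """Condition-level images: ``values[subject, condition, voxel]``."""

    values: np.ndarray            # (n_subjects, k, n_voxels)
    conditions: tuple[str, ...]
    grid: VoxelGrid
    subjects: tuple[int, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("values must be (subjects, conditions, voxels)")
        if v.shape[1] != len(self.conditions):
            raise ValueError("condition axis does not match labels")
        if v.shape[2] != self.grid.n_voxels:
            raise ValueError("voxel axis does not match grid")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite image values")
        object.__setattr__(self, "values", v)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def condition_index(self, label: str) -> int:
        try:
            return self.conditions.index(label)
        except ValueError:
            raise KeyError(f"condition {label!r} not present") from None


def gaussian_blob(grid: VoxelGrid, center_mm, fwhm_mm: float) -> np.ndarray:
    """Unit-norm Gaussian blob rasterized on the grid (flat, C order)."""
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    d2 = np.sum((grid.all_mm() - np.asarray(center_mm, float)) ** 2, axis=1)
    u = np.exp(-d2 / (2.0 * sigma ** 2))
    nrm = np.linalg.norm(u)
    if nrm == 0:
        raise ValueError("blob entirely outside the grid support")
    return u / nrm


def cube_indices(grid: VoxelGrid, center_mm, radius_voxels: int = 1) -> np.ndarray:
    """Flat indices of the (2r+1)^3 cube around a mm center, edge-clipped."""
    c = grid.mm_to_ijk(center_mm)
    if not grid.contains(c):
        raise ValueError(f"center {center_mm} maps outside the grid")
    r = radius_voxels
    lo = np.maximum(c - r, 0)
    hi = np.minimum(c + r, np.asarray(grid.shape) - 1)
    ii, jj, kk = np.meshgrid(*[np.arange(l, h + 1) for l, h in zip(lo, hi)],
                             indexing="ij")
    return np.ravel_multi_index(
        (ii.ravel(), jj.ravel(), kk.ravel()), grid.shape)


@dataclass(frozen=True)
class PlantedLV:
    """One rank-1 ground-truth task pattern."""

    amplitude: float
    task_profile: np.ndarray      # (k,), unit norm enforced
    spatial_map: np.ndarray       # (V,), unit norm enforced

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        for name in ("task_profile", "spatial_map"):
            vec = np.asarray(getattr(self, name), dtype=float)
            nrm = np.linalg.norm(vec)
            if nrm == 0:
                raise ValueError(f"{name} must be nonzero")
            object.__setattr__(self, name, vec / nrm)


@dataclass(frozen=True)
class SeedCoupling:
    """Planted seed-voxel coupling with per-condition correlation."""

    seed_center_mm: tuple[float, float, float]
    coupled_center_mm: tuple[float, float, float]
    r_by_condition: dict          # condition label -> target correlation
    radius_voxels: int = 1
    coupled_radius_voxels: int = 1

    def __post_init__(self) -> None:
        bad = {c: r for c, r in self.r_by_condition.items() if not abs(r) <= 1}
        if bad:
            raise ValueError(f"|r| must be <= 1, got {bad}")


@dataclass(frozen=True)
class PlantedModel:
    """Full generative model for a synthetic condition-image set."""

    planted_lvs: tuple[PlantedLV, ...] = ()
    seed_couplings: tuple[SeedCoupling, ...] = ()
    grand_mean: float = 0.0
    subject_sd: float = 0.25
    noise_sd: float = 0.25


def simulate_condition_images(
    n_subjects: int,
    conditions,
    grid: VoxelGrid,
    model: PlantedModel,
    rng_seed: int = 0,
) -> ConditionImageSet:
    """Draw a condition-image set from the planted generative model.

    ``X[s, c, :] = grand_mean + sum_l a_l v_l[c] u_l + subject offset
    + coupling terms + N(0, noise_sd)``. Coupling terms add a shared latent
    ``z[s, c]`` to both the seed cube and the coupled cube, scaled so the
    cross-subject correlation between any seed voxel and any coupled voxel
    equals ``r`` for that condition, given the total non-shared variance
    (noise + subject offsets).
    """
    rng = np.random.default_rng(rng_seed)
    conditions = tuple(conditions)
    k, V = len(conditions), grid.n_voxels
    X = np.full((n_subjects, k, V), float(model.grand_mean))

    for lv in model.planted_lvs:
        if lv.task_profile.size != k:
            raise ValueError("task profile length != number of conditions")
        if lv.spatial_map.size != V:
            raise ValueError("spatial map size != grid voxels")
        X += lv.amplitude * np.einsum("c,v->cv", lv.task_profile,
                                      lv.spatial_map)[None, :, :]

    # voxelwise subject offsets, shared across conditions
    if model.subject_sd > 0:
        X += rng.normal(0.0, model.subject_sd, size=(n_subjects, 1, V))

    sigma2_indep = model.noise_sd ** 2 + model.subject_sd ** 2
    for cp in model.seed_couplings:
        seed_idx = cube_indices(grid, cp.seed_center_mm, cp.radius_voxels)
        tgt_idx = cube_indices(grid, cp.coupled_center_mm,
                               cp.coupled_radius_voxels)
        z = rng.normal(0.0, 1.0, size=(n_subjects, k))
        # zero condition mean: the coupling factor is a subject-deviation
        # latent, so it induces correlation without shifting condition means
        z -= z.mean(axis=0, keepdims=True)
        z /= z.std(axis=0, keepdims=True)
        for ci, cond in enumerate(conditions):
            r = float(cp.r_by_condition.get(cond, 0.0))
            if r == 0.0:
                continue
            lam = np.sign(r) * np.sqrt(
                sigma2_indep * abs(r) / (1.0 - abs(r)))
            X[:, ci, seed_idx] += np.abs(lam) * z[:, ci, None]
            X[:, ci, tgt_idx] += lam * z[:, ci, None]

    if model.noise_sd > 0:
        X += rng.normal(0.0, model.noise_sd, size=X.shape)

    return ConditionImageSet(
        values=X, conditions=conditions, grid=grid,
        subjects=tuple(range(1, n_subjects + 1)),
    )


# ---------------------------------------------------------------------------
# Condition groupings for the two whole-brain analyses
# ---------------------------------------------------------------------------

# six modeled trial types, "<run_type>:<item_type>"; new = correct rejections
_OLD1, _OLD3, _OLDN = MODELED_CONDITIONS[0:3]
_NEW1, _NEW3, _NEWN = MODELED_CONDITIONS[3:6]

#: Condition groupings. The repetition analysis contrasts thrice- vs
#: once-studied hits (pooled over run types by default); the targetness
#: analysis contrasts memory targets (1x hits under incentivize-old, CRs
#: under incentivize-new) against non-targets (1x hits under
#: incentivize-new, CRs under incentivize-old), using 1x items only.
ANALYSIS_GROUPS = {
    "repetition": {"3x_hits": (_OLD3, _NEW3), "1x_hits": (_OLD1, _NEW1)},
    "targetness": {"targets": (_OLD1, _NEWN), "non_targets": (_NEW1, _OLDN)},
}


def select_conditions(
    images: ConditionImageSet,
    analysis: str,
    pooling: str = "pooled",
) -> ConditionImageSet:
    """Build the condition set entering a whole-brain PLS analysis.

    ``pooling="pooled"`` averages each group's two source conditions into a
    single condition (the default, giving a 2-condition contrast);
    ``"unpooled"`` keeps the 4 source conditions, labeled
    ``<group>/<source>`` so the 2+2 grouping stays recorded.
    """
    if analysis not in ANALYSIS_GROUPS:
        raise KeyError(f"unknown analysis {analysis!r}; "
                       f"expected one of {sorted(ANALYSIS_GROUPS)}")
    groups = ANALYSIS_GROUPS[analysis]
    idx = {c: images.condition_index(c)
           for g in groups.values() for c in g}

    if pooling == "pooled":
        labels, vals = [], []
        for gname, members in groups.items():
            labels.append(gname)
            vals.append(np.mean(
                [images.values[:, idx[c], :] for c in members], axis=0))
        values = np.stack(vals, axis=1)
    elif pooling == "unpooled":
        labels, vals = [], []
        for gname, members in groups.items():
            for c in members:
                labels.append(f"{gname}/{c}")
                vals.append(images.values[:, idx[c], :])
        values = np.stack(vals, axis=1)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")

    return ConditionImageSet(values=values, conditions=tuple(labels),
                             grid=images.grid, subjects=images.subjects)


def default_planted_model(
    grid: VoxelGrid | None = None,
    conditions=MODELED_CONDITIONS,
    amplitude: float = 2.5,
    coupling_r: float = 0.8,
) -> tuple[VoxelGrid, PlantedModel]:
    """A study-like ground truth on the desk-scale grid.

    Plants (a) a repetition pattern: a "ventral" blob loading on 3x hits
    against a "dorsal" blob loading on 1x hits; (b) a targetness pattern
    loading targets vs non-targets on two other blobs; (c) a seed coupling
    from an anterior-medial seed to the dorsal blob present only in the two
    target conditions, mirroring connectivity specific to target detection.
    """
    if grid is None:
        grid = VoxelGrid()
    conditions = tuple(conditions)
    k = len(conditions)

    def profile(plus, minus):
        v = np.zeros(k)
        for c in plus:
            v[conditions.index(c)] = 1.0
        for c in minus:
            v[conditions.index(c)] = -1.0
        return v / np.linalg.norm(v)

    ventral = gaussian_blob(grid, (5.0, -5.0, 5.0), fwhm_mm=5.0)
    dorsal = gaussian_blob(grid, (-5.0, 5.0, 5.0), fwhm_mm=5.0)
    rep_map = ventral - dorsal
    tgt_map = (gaussian_blob(grid, (5.0, 5.0, -5.0), fwhm_mm=5.0)
               - gaussian_blob(grid, (-5.0, -5.0, -5.0), fwhm_mm=5.0))

    model = PlantedModel(
        planted_lvs=(
            PlantedLV(amplitude, profile([_OLD3, _NEW3], [_OLD1, _NEW1]),
                      rep_map),
            PlantedLV(0.7 * amplitude, profile([_OLD1, _NEWN], [_NEW1, _OLDN]),
                      tgt_map),
        ),
        seed_couplings=(
            SeedCoupling(
                seed_center_mm=(-5.0, -1.0, -3.0),
                coupled_center_mm=(-5.0, 5.0, 5.0),
                r_by_condition={_OLD1: coupling_r, _NEWN: coupling_r},
            ),
        ),
    )
    return grid, model
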