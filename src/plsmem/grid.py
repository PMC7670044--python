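"""Voxel grid geometry: shape + affine mapping voxel indices to mm (RAS+)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from nibabel.affines import apply_affine


@dataclass(frozen=True)
class VoxelGrid:
    """A rectangular voxel grid with an invertible index->mm affine.

    Indices are 0-based; mm coordinates follow the RAS+ convention. The
    default is a desk-scale 10 x 10 x 10 grid of 2 mm isotropic voxels
    centered on the origin, standing in for an MNI-like space.
    """

    shape: tuple[int, int, int] = (10, 10, 10)
    affine: np.ndarray = field(default_factory=lambda: np.array([
        [2.0, 0.0, 0.0, -9.0],
        [0.0, 2.0, 0.0, -9.0],
        [0.0, 0.0, 2.0, -9.0],
        [0.0, 0.0, 0.0, 1.0],
    ]))

    def __post_init__(self) -> None:
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4) or abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "affine", aff)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def ijk_to_mm(self, ijk) -> np.ndarray:
        return apply_affine(self.affine, np.asarray(ijk, dtype=float))

    def mm_to_ijk(self, mm) -> np.ndarray:
        """Nearest voxel index for mm coordinates (may fall outside grid)."""
        ijk = apply_affine(np.linalg.inv(self.affine),
                           np.asarray(mm, dtype=float))
        return np.rint(ijk).astype(int)

    def contains(self, ijk) -> bool:
        ijk = np.asarray(ijk)
        return bool(np.all(ijk >= 0) and np.all(ijk < np.asarray(self.shape)))

    def ravel(self, ijk) -> int:
        """Flat voxel index (C order), the column order of data matrices."""
        return int(np.ravel_multi_index(tuple(np.asarray(ijk)), self.shape))

    def unravel(self, flat: int) -> tuple[int, int, int]:
        return tuple(int(i) for i in np.unravel_index(flat, self.shape))

    def all_mm(self) -> np.ndarray:
        """(n_voxels, 3) mm coordinates of every voxel in flat order."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.ijk_to_mm(idx)
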