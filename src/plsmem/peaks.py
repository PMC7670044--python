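"""Peak extraction from bootstrap-ratio maps.

Reports local maxima of |BSR| above threshold as a table of mm coordinates,
in the style of activation-peak tables (columns x, y, z, BSR).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import VoxelGrid
from .resampling import ReliabilityMap

PEAK_COLUMNS = ("lv_index", "sign", "x", "y", "z", "bsr")


def find_peaks(
    rel: ReliabilityMap | np.ndarray,
    grid: VoxelGrid,
    threshold: float | None = None,
    min_sep_mm: float = 10.0,
    lv_index: int | None = None,
) -> pd.DataFrame:
    """Local maxima of |BSR| above threshold, separated by >= min_sep_mm.

    Candidates are voxels that are local maxima of |BSR| in their 3x3x3
    neighborhood and exceed the threshold; they are accepted greedily by
    decreasing |BSR| (ties broken by lexicographic voxel index), skipping
    any candidate within ``min_sep_mm`` of an already-accepted peak. An
    empty table is valid output.
    """
    if isinstance(rel, ReliabilityMap):
        bsr = rel.bsr
        if threshold is None:
            threshold = rel.threshold
        if lv_index is None:
            lv_index = rel.lv_index
    else:
        bsr = np.asarray(rel, dtype=float)
        if threshold is None:
            threshold = 3.0
        if lv_index is None:
            lv_index = 0

    vol = np.abs(bsr).reshape(grid.shape)
    local_max = vol == ndimage.maximum_filter(vol, size=3, mode="constant",
                                              cval=-np.inf)
    cand = np.flatnonzero(local_max.ravel() & (vol.ravel() > threshold))
    # greedy order: decreasing |bsr|, then voxel index
    order = cand[np.lexsort((cand, -vol.ravel()[cand]))]

    accepted: list[int] = []
    accepted_mm: list[np.ndarray] = []
    for flat in order:
        mm = grid.ijk_to_mm(grid.unravel(int(flat)))
        if all(np.linalg.norm(mm - p) >= min_sep_mm for p in accepted_mm):
            accepted.append(int(flat))
            accepted_mm.append(mm)

    rows = []
    flat_bsr = bsr.ravel()
    for flat, mm in zip(accepted, accepted_mm):
        b = float(flat_bsr[flat])
        rows.append((lv_index, "+" if b > 0 else "-",
                     float(mm[0]), float(mm[1]), float(mm[2]), b))
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)
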