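"""Event-related BOLD simulation and GLM beta estimation.

A canonical double-gamma hemodynamic response function (HRF) is convolved
with per-condition boxcars to build the design matrix, per-voxel condition
amplitudes are recovered by ordinary least squares, and run-wise estimates
are averaged per condition. This is the per-subject stage that turns a
simulated test run into the condition-level beta images the PLS analyses
consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import ITEM_TYPES


class EstimationError(ValueError):
    """Design matrix unusable for least squares."""


@dataclass(frozen=True)
class HrfModel:
    """Sampled HRF kernel with unit peak amplitude."""

    tr: float
    kernel: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        if not np.all(np.isfinite(k)):
            raise ValueError("non-finite HRF kernel")
        object.__setattr__(self, "kernel", k)


def canonical_hrf(tr: float = 2.0, duration: float = 32.0) -> HrfModel:
    """Canonical double-gamma HRF sampled at the scan interval.

    Difference of two gamma densities (response peak near 5-6 s, undershoot
    near 16 s, undershoot amplitude 1/6 of the peak), normalized to unit
    peak. The kernel has ``duration / tr`` samples starting at t = 0.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    if duration < tr:
        raise ValueError("duration must be >= tr")
    n = int(round(duration / tr))
    t = np.arange(n) * tr
    peak = stats.gamma.pdf(t, a=6.0, scale=1.0)
    undershoot = stats.gamma.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    return HrfModel(tr=tr, kernel=h / h.max(), duration=duration)


@dataclass(frozen=True)
class DesignMatrix:
    """GLM design: (n_scans x n_regressors) values with named columns."""

    X: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.names):
            raise ValueError("column count does not match names")

    @property
    def rank_deficient(self) -> bool:
        return np.linalg.matrix_rank(self.X) < self.X.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]


def build_design_matrix(
    trials: pd.DataFrame,
    n_scans: int,
    hrf: HrfModel,
    conditions: tuple[str, ...] = ITEM_TYPES + ("null",),
    drift: bool = True,
) -> DesignMatrix:
    """Condition regressors from an events table.

    Each condition's regressor is the boxcar of its events (onset, word
    duration, at scan resolution with fractional occupancy at the edges)
    convolved with the HRF kernel and truncated to ``n_scans``. An
    intercept is always appended; a linear drift regressor is appended by
    default. Conditions without events yield a zero regressor. Raises if
    the resulting matrix is rank deficient (ignoring all-zero columns).
    """
    tr_ms = hrf.tr * 1000.0
    if (trials["onset_ms"] >= n_scans * tr_ms).any():
        raise ValueError("event onset beyond the run duration")
    cols, names = [], []
    for cond in conditions:
        box = np.zeros(n_scans)
        for ev in trials[trials["item_type"] == cond].itertuples():
            a = ev.onset_ms / tr_ms
            b = (ev.onset_ms + ev.duration_ms) / tr_ms
            for scan in range(int(a), min(int(np.ceil(b)), n_scans)):
                box[scan] += min(b, scan + 1) - max(a, scan)
        reg = np.convolve(box, hrf.kernel)[:n_scans]
        cols.append(reg)
        names.append(cond)
    cols.append(np.ones(n_scans))
    names.append("intercept")
    if drift:
        cols.append(np.linspace(-1.0, 1.0, n_scans))
        names.append("drift")
    X = np.column_stack(cols)
    nonzero = np.any(X != 0, axis=0)
    if np.linalg.matrix_rank(X[:, nonzero]) < int(nonzero.sum()):
        raise EstimationError("design matrix is rank deficient")
    return DesignMatrix(X=X, names=tuple(names))


def simulate_bold(
    design: DesignMatrix,
    betas: dict[str, np.ndarray],
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> np.ndarray:
    """BOLD time series X @ B + white noise, (n_scans x n_voxels)."""
    rng = np.random.default_rng(rng_seed)
    V = len(next(iter(betas.values())))
    B = np.zeros((design.X.shape[1], V))
    for name, vals in betas.items():
        B[design.names.index(name)] = vals
    ts = design.X @ B
    if noise_sd > 0:
        ts = ts + rng.normal(0.0, noise_sd, size=ts.shape)
    return ts


def estimate_betas(ts: np.ndarray, design: DesignMatrix) -> dict[str, np.ndarray]:
    """Per-voxel OLS estimates for every regressor, keyed by name."""
    if ts.shape[0] != design.X.shape[0]:
        raise ValueError("scan count mismatch between data and design")
    if ts.shape[0] <= design.X.shape[1]:
        raise EstimationError("more regressors than scans")
    nonzero = np.any(design.X != 0, axis=0)
    if np.linalg.matrix_rank(design.X[:, nonzero]) < int(nonzero.sum()):
        raise EstimationError("design matrix is rank deficient")
    B, *_ = np.linalg.lstsq(design.X, ts, rcond=None)
    return {name: B[i] for i, name in enumerate(design.names)}


def average_condition_betas(
    run_betas: list[dict[str, np.ndarray]],
    conditions: tuple[str, ...],
) -> np.ndarray:
    """Average run-wise beta maps per condition, (k x n_voxels)."""
    return np.stack([
        np.mean([rb[c] for rb in run_betas if c in rb], axis=0)
        for c in conditions
    ])
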