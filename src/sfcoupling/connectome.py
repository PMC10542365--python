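"""Functional connectomes, density thresholding, and structure-function coupling.

Structure-function coupling (SFC) of region *i* is the correlation between
row *i* of the structural connectome and row *i* of the functional
connectome, excluding the self-connection and any entry where either the
structural or the functional value equals zero.  Its temporal variance is
the variance of the window-wise SFC values over contiguous non-overlapping
windows of the scan (default 20).  Undefined values propagate as NaN, never
silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "StructuralConnectome",
    "FunctionalConnectome",
    "WindowedFC",
    "CouplingMap",
    "VarianceMap",
    "compute_fc",
    "window_fc",
    "threshold_density",
    "regional_sfc",
    "temporal_sfc_variance",
]


@dataclass(frozen=True)
class StructuralConnectome:
    """Symmetric nonnegative weighted connectivity matrix, zero diagonal."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-9):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class FunctionalConnectome:
    """Region-by-region correlation matrix (unit diagonal)."""

    corr: np.ndarray

    def __post_init__(self) -> None:
        c = self.corr
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("corr must be square")
        if not np.allclose(c, c.T, atol=1e-9):
            raise ValueError("corr must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("diagonal must be 1")
        if np.any(np.abs(c) > 1 + 1e-9):
            raise ValueError("entries must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.corr.shape[0]


@dataclass(frozen=True)
class WindowedFC:
    """Stack of window-wise functional connectomes.

    ``stack`` has shape (W, R, R); ``window_bounds`` holds the half-open
    timepoint intervals, contiguous and equal-length.
    """

    stack: np.ndarray
    window_bounds: tuple

    @property
    def n_windows(self) -> int:
        return self.stack.shape[0]


@dataclass(frozen=True)
class CouplingMap:
    """Per-region SFC values; NaN marks regions with too few valid pairs."""

    sfc: np.ndarray
    n_valid: np.ndarray


@dataclass(frozen=True)
class VarianceMap:
    """Per-region temporal SFC variance; NaN where < 2 windows are defined."""

    var_sfc: np.ndarray
    n_windows_used: np.ndarray


def compute_fc(panel) -> FunctionalConnectome:
    """Static functional connectome: pairwise Pearson correlation of rows."""
    x = np.asarray(panel.values, dtype=float)
    sd = x.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance series for region(s) {bad.tolist()}")
    c = np.corrcoef(x)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return FunctionalConnectome(c)


def window_fc(panel, n_windows: int = 20) -> WindowedFC:
    """Split the panel into contiguous non-overlapping windows and correlate each.

    Window length is ``floor(T / n_windows)``; trailing remainder timepoints
    are discarded.
    """
    t = panel.n_timepoints
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    length = t // n_windows
    if length < 3:
        raise ValueError(
            f"too few timepoints per window ({length}); need floor(T/W) >= 3"
        )
    bounds = tuple((w * length, (w + 1) * length) for w in range(n_windows))
    stack = np.empty((n_windows, panel.n_regions, panel.n_regions))
    for w, (a, b) in enumerate(bounds):
        seg = panel.values[:, a:b]
        sd = seg.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(seg)
        c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(c, 1.0)
        c[sd == 0, :] = np.nan
        c[:, sd == 0] = np.nan
        stack[w] = c
    return WindowedFC(stack=stack, window_bounds=bounds)


def threshold_density(sc: StructuralConnectome, keep_fraction: float = 0.7) -> StructuralConnectome:
    """Keep the strongest ``keep_fraction`` of unique nonzero edges.

    The retained count is ``ceil(keep_fraction * n_nonzero)``.  Ties at the
    cutoff are broken deterministically by (weight descending, then
    lexicographic edge index ascending).
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    w = sc.weights
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    nz = np.flatnonzero(vals > 0)
    n_keep = int(np.ceil(keep_fraction * len(nz)))
    # stable sort by descending weight; ties fall back to edge-index order
    order = nz[np.argsort(-vals[nz], kind="stable")]
    keep = order[:n_keep]
    out = np.zeros_like(w)
    out[iu[keep], ju[keep]] = vals[keep]
    out += out.T
    return StructuralConnectome(out)


def _masked_corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    with np.errstate(invalid="ignore", divide="ignore"):
        if method == "pearson":
            r = sps.pearsonr(a, b).statistic
        else:
            r = sps.spearmanr(a, b).statistic
    return float(r)


def regional_sfc(
    sc: StructuralConnectome,
    fc: FunctionalConnectome,
    method: str = "pearson",
    min_pairs: int = 3,
) -> CouplingMap:
    """Per-region structure-function coupling.

    For region *i*, correlates ``sc.weights[i]`` with ``fc.corr[i]`` over
    indices *j* with ``j != i`` and both entries nonzero (and finite), using
    Pearson (atlas convention) or Spearman (voxel convention) correlation.
    Regions with fewer than ``min_pairs`` surviving entries (or a constant
    surviving row) are NaN.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if sc.n_regions != fc.n_regions:
        raise ValueError("structural and functional connectomes differ in size")
    return _sfc_from_matrices(sc.weights, fc.corr, method, min_pairs)


def _sfc_from_matrices(
    sw: np.ndarray, fw: np.ndarray, method: str, min_pairs: int
) -> CouplingMap:
    n = sw.shape[0]
    sfc = np.full(n, np.nan)
    n_valid = np.zeros(n, dtype=int)
    for i in range(n):
        srow, frow = sw[i], fw[i]
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        mask &= (srow != 0) & (frow != 0)
        mask &= np.isfinite(srow) & np.isfinite(frow)
        n_valid[i] = int(mask.sum())
        if n_valid[i] < min_pairs:
            continue
        a, b = srow[mask], frow[mask]
        if a.std() == 0 or b.std() == 0:
            continue
        sfc[i] = _masked_corr(a, b, method)
    return CouplingMap(sfc=sfc, n_valid=n_valid)


def temporal_sfc_variance(
    sc: StructuralConnectome,
    wfc: WindowedFC,
    method: str = "pearson",
    min_pairs: int = 3,
    ddof: int = 1,
) -> VarianceMap:
    """Variance of window-wise SFC per region.

    The exclusion mask (self-connection, zero entries) is recomputed within
    each window; windows where a region is undefined are skipped.  Regions
    with fewer than 2 defined windows are NaN.  ``ddof=1`` gives the sample
    variance (default); ``ddof=0`` the population variance.
    """
    if wfc.n_windows < 2:
        raise ValueError("need at least 2 windows for a variance")
    if ddof not in (0, 1):
        raise ValueError("ddof must be 0 or 1")
    n = sc.n_regions
    per_window = np.full((wfc.n_windows, n), np.nan)
    for w in range(wfc.n_windows):
        per_window[w] = _sfc_from_matrices(
            sc.weights, wfc.stack[w], method, min_pairs
        ).sfc
    n_used = np.sum(np.isfinite(per_window), axis=0)
    var = np.full(n, np.nan)
    for i in range(n):
        vals = per_window[np.isfinite(per_window[:, i]), i]
        if len(vals) >= 2:
            var[i] = float(np.var(vals, ddof=ddof))
    return VarianceMap(var_sfc=var, n_windows_used=n_used)
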