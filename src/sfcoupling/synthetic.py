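"""Synthetic cortical cohorts with known ground truth.

This module generates everything the downstream analysis consumes: a region
set with unit-sphere coordinates and hierarchy annotations, a
distance/gradient-dependent structural connectome, regional BOLD-like time
series with prescribed Hurst exponents and prescribed coupling to the
structural backbone, and a voxel lattice of neighbour transition
probabilities.  Because the generating parameters (hierarchy gradient,
per-region Hurst exponent, coupling level, myelin-gradient correlation) are
known exactly, every statistic the pipeline computes can be validated by
parameter recovery.

All generators are pure functions of their arguments including the seed:
regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._rng import substream

__all__ = [
    "RegionSet",
    "GroundTruth",
    "TimeSeriesPanel",
    "TransitionField",
    "NEIGHBOR_OFFSETS",
    "make_region_set",
    "simulate_structural_connectome",
    "simulate_fgn",
    "fgn_autocovariance",
    "simulate_bold_panel",
    "simulate_transition_field",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionSet:
    """Cortical regions with coordinates and hierarchy annotations.

    Attributes
    ----------
    region_id : (R,) int array of unique labels.
    hemisphere : (R,) array of ``"left"`` / ``"right"``.
    xyz : (R, 3) unit-sphere coordinates.
    gradient : (R,) continuous hierarchy scalar (arbitrary units; low =
        sensory/unimodal analogue, high = association/transmodal analogue).
    class_label : (R,) int in ``0..k-1`` — coarse cyto-architectonic class
        analogue obtained by quantile-binning the gradient.
    myelin : (R,) positive scalar, the T1w/T2w-ratio proxy.
    """

    region_id: np.ndarray
    hemisphere: np.ndarray
    xyz: np.ndarray
    gradient: np.ndarray
    class_label: np.ndarray
    myelin: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.region_id)
        if len(np.unique(self.region_id)) != n:
            raise ValueError("region ids must be unique")
        norms = np.linalg.norm(self.xyz, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("coordinates must lie on the unit sphere")
        for hemi in ("left", "right"):
            if not np.any(self.hemisphere == hemi):
                raise ValueError(f"{hemi} hemisphere is empty")
        if np.any(self.myelin <= 0):
            raise ValueError("myelin proxy must be positive")

    @property
    def n_regions(self) -> int:
        return len(self.region_id)


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of a synthetic cohort, for recovery tests."""

    h_true: np.ndarray
    coupling: np.ndarray
    gradient_myelin_corr: float
    params: dict
    seed: int

    def __post_init__(self) -> None:
        if np.any((self.h_true <= 0) | (self.h_true >= 1)):
            raise ValueError("true Hurst exponents must lie strictly in (0, 1)")


@dataclass(frozen=True)
class TimeSeriesPanel:
    """Regions x timepoints panel of (synthetic) BOLD signal.

    ``tr`` is the sampling interval in seconds; rows are demeaned,
    unit-variance series.
    """

    values: np.ndarray
    tr: float = 0.72

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("panel must be 2-D (regions x timepoints)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("panel contains non-finite values")
        if np.any(self.values.std(axis=1) == 0):
            raise ValueError("every region's series must have nonzero variance")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


# 26 lattice neighbour offsets in fixed lexicographic order over
# (dx, dy, dz) in {-1,0,1}^3 \ {0}; this order defines the channel axis of
# TransitionField.probs.
NEIGHBOR_OFFSETS: np.ndarray = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=int,
)


@dataclass(frozen=True)
class TransitionField:
    """3-D voxel lattice with 26-neighbour fibre transition probabilities.

    ``probs[x, y, z, k]`` is the probability of stepping from voxel
    ``(x, y, z)`` to its neighbour at offset ``NEIGHBOR_OFFSETS[k]``.
    Transitions out of the cortical mask (or off the lattice) are zero.
    """

    probs: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.probs.ndim != 4 or self.probs.shape[3] != 26:
            raise ValueError("probs must have shape (X, Y, Z, 26)")
        if self.mask.shape != self.probs.shape[:3]:
            raise ValueError("mask shape must match the lattice")
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if np.any(self.probs[~self.mask] != 0):
            raise ValueError("masked voxels must have zero outgoing probability")

    @property
    def shape(self) -> tuple:
        return self.probs.shape[:3]


# ---------------------------------------------------------------------------
# region set
# ---------------------------------------------------------------------------


def _fibonacci_half_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the upper (z > 0) half of the unit sphere."""
    i = np.arange(n)
    z = (i + 0.5) / n  # strictly inside (0, 1)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


def make_region_set(
    n_regions: int,
    k_classes: int = 5,
    smoothness: float = 0.5,
    seed: int = 0,
    gradient_noise: float = 0.3,
    myelin_slope: float = -0.3,
    myelin_noise: float = 0.45,
) -> RegionSet:
    """Generate a bilateral region set with hierarchy annotations.

    Each hemisphere is a Fibonacci lattice on a half-sphere (left: x < 0,
    right: x > 0, mirror-symmetric).  The hierarchy gradient is the angular
    distance from the hemisphere pole plus a Gaussian-process perturbation
    with great-circle length-scale ``smoothness`` (radians), standardized.
    Class labels are gradient quantile bins; the myelin proxy is an affine
    function of the standardized gradient (slope ``myelin_slope``, so the
    default is anti-correlated, as for T1w/T2w along the sensory-association
    axis) plus Gaussian noise, clipped positive.
    """
    if n_regions % 2 != 0:
        raise ValueError("n_regions must be even (split across hemispheres)")
    if n_regions < 2 * k_classes:
        raise ValueError("n_regions must be at least 2 * k_classes")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")

    half = n_regions // 2
    base = _fibonacci_half_sphere(half)
    # rotate the pole (0,0,1) onto (-1,0,0) for the left hemisphere
    rot = np.array([[0.0, 0.0, -1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
    left = base @ rot.T
    right = left * np.array([-1.0, 1.0, 1.0])  # mirror through the sagittal plane
    xyz = np.vstack([left, right])
    hemisphere = np.array(["left"] * half + ["right"] * half)

    # angular distance from each hemisphere's pole
    poles = np.where(hemisphere[:, None] == "left", [-1.0, 0.0, 0.0], [1.0, 0.0, 0.0])
    base_grad = np.arccos(np.clip(np.sum(xyz * poles, axis=1), -1.0, 1.0))

    rng = substream(seed, "region_set")
    # GP noise with squared-exponential covariance in great-circle distance
    gcd = np.arccos(np.clip(xyz @ xyz.T, -1.0, 1.0))
    cov = np.exp(-0.5 * (gcd / smoothness) ** 2) + 1e-8 * np.eye(n_regions)
    noise = np.linalg.cholesky(cov) @ rng.standard_normal(n_regions)

    gradient = _zscore(_zscore(base_grad) + gradient_noise * _zscore(noise))

    # quantile bins: equal-size groups in gradient order (stable)
    order = np.argsort(gradient, kind="stable")
    class_label = np.empty(n_regions, dtype=int)
    for k, chunk in enumerate(np.array_split(order, k_classes)):
        class_label[chunk] = k

    myelin = 1.5 + myelin_slope * gradient + myelin_noise * rng.standard_normal(n_regions)
    myelin = np.clip(myelin, 0.05, None)

    return RegionSet(
        region_id=np.arange(n_regions),
        hemisphere=hemisphere,
        xyz=xyz,
        gradient=gradient,
        class_label=class_label,
        myelin=myelin,
    )


# ---------------------------------------------------------------------------
# structural connectome
# ---------------------------------------------------------------------------


def simulate_structural_connectome(
    regions: RegionSet,
    decay: float = 3.0,
    density: float = 0.35,
    seed: int = 0,
    gradient_decay: float = 1.0,
    weight_noise: float = 0.5,
):
    """Distance- and gradient-dependent random structural connectome.

    Expected edge weight decays exponentially with great-circle distance
    (rate ``decay``, per radian) and with hierarchy-gradient mismatch
    (rate ``gradient_decay``); multiplicative log-normal noise
    (``weight_noise`` = sigma of log-weight) makes rows distinct.  The
    weakest edges are removed until the off-diagonal density matches
    ``density``.  Output is symmetric, nonnegative, zero-diagonal.
    """
    from .connectome import StructuralConnectome  # local import: avoid cycle

    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    if decay <= 0:
        raise ValueError("decay must be positive")

    rng = substream(seed, "structural_connectome")
    xyz, grad = regions.xyz, regions.gradient
    n = regions.n_regions
    d = np.arccos(np.clip(xyz @ xyz.T, -1.0, 1.0))
    dg = np.abs(grad[:, None] - grad[None, :])
    w = np.exp(-decay * d - gradient_decay * dg)

    iu = np.triu_indices(n, k=1)
    noise = np.exp(weight_noise * rng.standard_normal(len(iu[0])))
    vals = w[iu] * noise

    n_edges = len(vals)
    n_keep = int(np.ceil(density * n_edges))
    if n_keep < n_edges:
        cutoff = np.sort(vals)[n_edges - n_keep]
        vals = np.where(vals >= cutoff, vals, 0.0)

    out = np.zeros((n, n))
    out[iu] = vals
    out += out.T
    return StructuralConnectome(out)


# ---------------------------------------------------------------------------
# fractional Gaussian noise
# ---------------------------------------------------------------------------


def fgn_autocovariance(H: float, lags: np.ndarray) -> np.ndarray:
    """Autocovariance gamma(k) of unit-variance fGn with Hurst exponent H."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * H
    return 0.5 * (np.abs(k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)


def simulate_fgn(H: float, n: int, seed) -> np.ndarray:
    """Exact stationary fractional Gaussian noise by circulant embedding.

    Embeds the length-``n`` autocovariance in a circulant matrix of order
    ``2n`` (Davies-Harte); when the embedding spectrum is nonnegative the
    sample has exactly the fGn covariance with unit variance.  Negative
    spectral values (possible only at extreme ``H`` with tiny ``n``) are
    truncated at zero with a warning.

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if not 0 < H < 1:
        raise ValueError("H must lie strictly in (0, 1)")
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "fgn")

    g = fgn_autocovariance(H, np.arange(n + 1))
    row = np.concatenate([g[:n], g[n:0:-1]])  # circulant first row, length 2n
    lam = np.fft.fft(row).real
    if np.any(lam < -1e-9 * lam.max()):
        warnings.warn(
            "circulant embedding not nonnegative definite; "
            "negative spectral values truncated at zero",
            RuntimeWarning,
            stacklevel=2,
        )
    lam = np.clip(lam, 0.0, None)

    m = 2 * n
    a = np.zeros(m, dtype=complex)
    a[0] = np.sqrt(lam[0]) * rng.standard_normal()
    a[n] = np.sqrt(lam[n]) * rng.standard_normal()
    u = rng.standard_normal(n - 1)
    v = rng.standard_normal(n - 1)
    a[1:n] = np.sqrt(lam[1:n] / 2.0) * (u + 1j * v)
    a[n + 1 :] = np.conj(a[1:n][::-1])
    x = np.fft.fft(a) / np.sqrt(m)
    return x[:n].real


# ---------------------------------------------------------------------------
# BOLD panel
# ---------------------------------------------------------------------------


def simulate_bold_panel(
    regions: RegionSet,
    sc,
    H_profile: np.ndarray,
    coupling_profile: np.ndarray,
    n_timepoints: int = 1200,
    seed: int = 0,
    tr: float = 0.72,
) -> tuple[TimeSeriesPanel, GroundTruth]:
    """Regional time series with prescribed Hurst exponents and SC coupling.

    Region ``i``'s series is

        sqrt(c_i) * shared_i + sqrt(1 - c_i) * private_i

    where ``private_i`` is fGn with exponent ``H_profile[i]``, ``shared_i``
    is the standardized SC-row-weighted mixture of one latent fGn source per
    region (source ``j`` carries exponent ``H_profile[j]``), and
    ``c_i = coupling_profile[i]``.  Strongly connected region pairs share
    similar mixtures, so functional connectivity mirrors the structural
    backbone exactly to the degree the coupling profile dictates: higher
    ``c_i`` yields higher expected structure-function coupling for region
    ``i``.  Rows are returned demeaned with unit variance.
    """
    H_profile = np.asarray(H_profile, dtype=float)
    coupling = np.asarray(coupling_profile, dtype=float)
    n = regions.n_regions
    if H_profile.shape != (n,) or coupling.shape != (n,):
        raise ValueError("profiles must match the region count")
    if np.any((coupling < 0) | (coupling > 1)):
        raise ValueError("coupling values must lie in [0, 1]")
    if np.any((H_profile <= 0) | (H_profile >= 1)):
        raise ValueError("Hurst profile must lie strictly in (0, 1)")

    rng = substream(seed, "bold_panel")
    latent = np.vstack([simulate_fgn(h, n_timepoints, rng) for h in H_profile])
    private = np.vstack([simulate_fgn(h, n_timepoints, rng) for h in H_profile])

    w = sc.weights
    shared = w @ latent
    for i in range(n):
        s = shared[i].std()
        if s > 0:
            shared[i] = (shared[i] - shared[i].mean()) / s
        else:  # isolated region: fall back to its own latent source
            shared[i] = latent[i]

    x = np.sqrt(coupling)[:, None] * shared + np.sqrt(1.0 - coupling)[:, None] * private
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)

    truth = GroundTruth(
        h_true=H_profile.copy(),
        coupling=coupling.copy(),
        gradient_myelin_corr=float(np.corrcoef(regions.gradient, regions.myelin)[0, 1]),
        params={"n_timepoints": n_timepoints, "tr": tr},
        seed=int(seed),
    )
    return TimeSeriesPanel(values=x, tr=tr), truth


# ---------------------------------------------------------------------------
# transition field
# ---------------------------------------------------------------------------


def simulate_transition_field(
    shape: tuple,
    anisotropy: float = 0.0,
    seed: int = 0,
    smoothness: float = 1.0,
    mask: np.ndarray | None = None,
) -> TransitionField:
    """Smooth random 26-neighbour transition-probability field.

    Log-probabilities are a Gaussian random field (smoothed with a spatial
    Gaussian kernel of width ``smoothness`` voxels) plus ``anisotropy`` times
    the x-component of the unit step direction, so positive anisotropy
    favours +x steps.  Probabilities out of the lattice or into masked
    voxels are zero; each in-mask voxel's outgoing probabilities are
    normalized to sum to one (when any neighbour is reachable).
    """
    from scipy.ndimage import gaussian_filter

    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 2 for s in shape):
        raise ValueError("shape must be 3-D with every dimension >= 2")
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape must match the lattice")

    rng = substream(seed, "transition_field")
    logits = rng.standard_normal(shape + (26,))
    if smoothness > 0:
        for k in range(26):
            logits[..., k] = gaussian_filter(logits[..., k], sigma=smoothness)
    unit = NEIGHBOR_OFFSETS / np.linalg.norm(NEIGHBOR_OFFSETS, axis=1, keepdims=True)
    logits += anisotropy * unit[:, 0]

    p = np.exp(logits)
    # zero out transitions leaving the lattice or entering a masked voxel
    idx = np.indices(shape)  # (3, X, Y, Z)
    for k, off in enumerate(NEIGHBOR_OFFSETS):
        tgt = idx + off[:, None, None, None]
        inside = np.all((tgt >= 0) & (tgt < np.array(shape)[:, None, None, None]), axis=0)
        valid = np.zeros(shape, dtype=bool)
        ti = tuple(np.clip(tgt[d], 0, shape[d] - 1) for d in range(3))
        valid[inside] = mask[ti][inside]
        p[..., k] = np.where(valid, p[..., k], 0.0)
    p[~mask] = 0.0

    total = p.sum(axis=3, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, p / total, 0.0)
    return TransitionField(probs=p, mask=mask)
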