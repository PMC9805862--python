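"""Global functional connectivity density (gFCD) mapping.

For every gray-matter voxel *i*, K[i] counts the voxels *j* (j != i, also in
gray matter) whose Pearson correlation with *i* strictly exceeds a positive
threshold (0.6 by default; 0.4 and 0.5 as robustness settings).  Negative
correlations never count and the self-pair is excluded.  K is normalized by
its gray-matter mean K0, so mean(K/K0) over the mask is identically 1.
Correlations are evaluated blockwise so memory stays O(block_size x V).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simdata import BoldSeries

__all__ = ["GfcdParams", "GfcdMap", "compute_gfcd", "gfcd_region_mean", "gfcd_naive"]


@dataclass(frozen=True)
class GfcdParams:
    r_threshold: float = 0.6
    block_size: int = 2000

    def __post_init__(self) -> None:
        if not 0.0 < self.r_threshold < 1.0:
            raise ValueError("r_threshold must lie in (0, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be positive")


@dataclass
class GfcdMap:
    """Edge counts K and normalized density K/K0 on the gray-matter mask."""

    K: np.ndarray               # 3D int, zero outside mask
    K_norm: np.ndarray          # 3D float, zero outside mask
    mask: np.ndarray
    r_threshold: float

    def region_values(self, region_mask: np.ndarray, normalized: bool = True) -> np.ndarray:
        m = region_mask & self.mask
        if not m.any():
            raise ValueError("region does not intersect the gray-matter mask")
        return (self.K_norm if normalized else self.K)[m]


def _unit_rows(ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-center and scale rows to unit norm; zero-variance rows -> zero rows.

    "Zero variance" uses a relative tolerance so constant rows whose mean is
    not exactly representable still count as flat.
    """
    centered = ts - ts.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    scale = np.abs(ts).max(axis=1) + 1.0
    zero = norms <= 1e-10 * scale
    norms[zero] = 1.0
    out = centered / norms[:, None]
    out[zero] = 0.0
    return out, zero


def compute_gfcd(cleaned: BoldSeries, gm_mask: np.ndarray, params: GfcdParams = GfcdParams()) -> GfcdMap:
    """Blockwise per-voxel edge count over the gray-matter mask.

    ``K[i] = #{ j != i in mask : r_ij > r_threshold }``; zero-variance
    voxels get K = 0 with a warning (their correlation is undefined, so
    they form no edges in either direction).  The result is independent of
    ``block_size``.
    """
    if gm_mask.shape != cleaned.grid_shape:
        raise ValueError("gray-matter mask must share the BOLD grid")
    if not gm_mask.any():
        raise ValueError("gray-matter mask is empty")
    if cleaned.n_volumes < 3:
        raise ValueError("need at least 3 retained volumes for correlations")
    ts = cleaned.data[gm_mask]                  # (v, t)
    Z, zero = _unit_rows(ts.astype(float))
    if zero.all():
        raise ValueError("all gray-matter voxels have zero variance")
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance voxels assigned K=0", stacklevel=2)

    v = Z.shape[0]
    K = np.zeros(v, dtype=np.int64)
    thr = params.r_threshold
    for start in range(0, v, params.block_size):
        stop = min(start + params.block_size, v)
        corr = Z[start:stop] @ Z.T              # (b, v)
        counts = (corr > thr).sum(axis=1)
        # remove the self-pair (self-correlation 1 > thr) for valid voxels
        counts -= ~zero[start:stop]
        K[start:stop] = counts
    K[zero] = 0

    k0 = K.mean()
    K_norm = K / k0 if k0 > 0 else np.zeros_like(K, dtype=float)
    out_K = np.zeros(cleaned.grid_shape, dtype=np.int64)
    out_K[gm_mask] = K
    out_norm = np.zeros(cleaned.grid_shape, dtype=float)
    out_norm[gm_mask] = K_norm
    return GfcdMap(K=out_K, K_norm=out_norm, mask=gm_mask.copy(), r_threshold=thr)


def gfcd_naive(cleaned: BoldSeries, gm_mask: np.ndarray, r_threshold: float) -> np.ndarray:
    """O(V^2) double-loop reference count (oracle for small masks).

    Uses :func:`numpy.corrcoef` for the correlation matrix and an explicit
    pair loop for the counting, sharing no code with the blockwise path.
    Zero-variance voxels yield NaN correlations, which never pass the
    strict threshold.
    """
    ts = cleaned.data[gm_mask].astype(float)
    v = ts.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(ts)
    K = np.zeros(v, dtype=np.int64)
    for i in range(v):
        for j in range(v):
            if i != j and C[i, j] > r_threshold:
                K[i] += 1
    return K


def gfcd_region_mean(gfcd_map3d: np.ndarray, region_mask: np.ndarray, gm_mask: np.ndarray) -> float:
    """Arithmetic mean of a (typically smoothed) K/K0 map over a region."""
    m = region_mask & gm_mask
    if not m.any():
        raise ValueError("region does not intersect the gray-matter mask")
    return float(gfcd_map3d[m].mean())
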