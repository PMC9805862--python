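"""Seed-based functional connectivity with Fisher's z transform.

The seed time course is the unweighted mean of the preprocessed BOLD signal
over the seed voxels; every brain voxel's Pearson correlation with it is
mapped through atanh (Fisher z), which stabilizes the sampling variance to
approximately 1/(T-3) under independence.  |r| is clamped just below 1 so
seed self-voxels stay finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .simdata import BoldSeries

__all__ = ["FcMap", "extract_seed_timecourse", "seed_fc_map", "fc_region_mean", "R_CLAMP"]

R_CLAMP = 1.0 - 1e-7


@dataclass
class FcMap:
    """Voxel-wise Fisher-z connectivity to a seed region."""

    z: np.ndarray               # 3D float, 0 outside brain mask
    brain_mask: np.ndarray
    seed_mask: np.ndarray
    n_volumes: int
    meta: dict = field(default_factory=dict)


def extract_seed_timecourse(cleaned: BoldSeries, seed_mask: np.ndarray) -> np.ndarray:
    """Unweighted mean series over the seed voxels."""
    if seed_mask.shape != cleaned.grid_shape:
        raise ValueError("seed mask must share the BOLD grid")
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    return cleaned.data[seed_mask].mean(axis=0)


def seed_fc_map(
    cleaned: BoldSeries,
    seed_mask: np.ndarray,
    brain_mask: np.ndarray,
    meta: dict | None = None,
) -> FcMap:
    """Fisher-z map of every brain voxel's correlation with the seed mean.

    Zero-variance voxels get z = 0 with a warning; a zero-variance seed
    mean is an error.
    """
    if cleaned.n_volumes < 3:
        raise ValueError("need at least 3 volumes")
    if brain_mask.shape != cleaned.grid_shape:
        raise ValueError("brain mask must share the BOLD grid")
    seed_ts = extract_seed_timecourse(cleaned, seed_mask)
    seed_ts = seed_ts - seed_ts.mean()
    seed_norm = np.linalg.norm(seed_ts)
    if seed_norm == 0:
        raise ValueError("seed mean time course has zero variance")
    s = seed_ts / seed_norm

    ts = cleaned.data[brain_mask].astype(float)
    centered = ts - ts.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    zero = norms <= 1e-10 * (np.abs(ts).max(axis=1) + 1.0)
    centered[zero] = 0.0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance voxels assigned z=0", stacklevel=2)
    norms[zero] = 1.0
    r = centered @ s / norms
    r[zero] = 0.0
    r = np.clip(r, -R_CLAMP, R_CLAMP)
    z = np.arctanh(r)

    out = np.zeros(cleaned.grid_shape, dtype=float)
    out[brain_mask] = z
    return FcMap(z=out, brain_mask=brain_mask.copy(), seed_mask=seed_mask.copy(),
                 n_volumes=cleaned.n_volumes, meta=dict(meta or {}))


def fc_region_mean(z_map3d: np.ndarray, region_mask: np.ndarray) -> float:
    """Mean (typically smoothed) Fisher-z over a region."""
    if not region_mask.any():
        raise ValueError("region mask is empty")
    return float(np.asarray(z_map3d)[region_mask].mean())
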