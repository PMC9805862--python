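"""Session-level denoising and quality control.

The chain mirrors a standard CompCor-based resting-state pipeline operating
on already aligned data: discard initial volumes, build a nuisance design
(5 pooled WM+CSF principal components, 12 motion regressors, linear trend,
intercept, plus one indicator column per scrubbed volume), remove it in a
single least-squares regression per voxel, then band-pass the residuals to
0.01-0.1 Hz with a zero-phase Butterworth filter.  The global signal is
never regressed.  Derived 3D maps (not raw series) are smoothed with a
Gaussian kernel parameterized by FWHM in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .simdata import BoldSeries, MotionTrace

__all__ = [
    "NuisanceMatrix",
    "QcThresholds",
    "QcReport",
    "discard_initial_volumes",
    "compcor_components",
    "motion_regressors",
    "framewise_displacement",
    "flag_bad_volumes",
    "qc_exclusion",
    "build_nuisance",
    "clean_timeseries",
    "smooth_map",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class NuisanceMatrix:
    """Per-volume nuisance design: columns + labels."""

    regressors: np.ndarray            # (t, k)
    labels: list

    def __post_init__(self) -> None:
        if self.regressors.shape[1] != len(self.labels):
            raise ValueError("labels must match regressor columns")
        if not np.all(np.isfinite(self.regressors)):
            raise ValueError("nuisance regressors must be finite")


@dataclass(frozen=True)
class QcThresholds:
    """Scrubbing and exclusion thresholds (ART 'intermediate' style defaults)."""

    fd_mm: float = 0.9                 # composite framewise displacement
    global_z: float = 5.0              # |z| of global-mean intensity change
    rotation_radius_mm: float = 65.0   # converts rotations to arc displacement
    bad_fraction_max: float = 0.30     # subject/condition exclusion, strict >
    max_translation_mm: float = 3.0    # subject/condition exclusion, strict >


@dataclass
class QcReport:
    bad_volume_fraction: float
    max_abs_translation_mm: float
    max_abs_rotation_rad: float
    excluded: bool
    reason: str = ""


def discard_initial_volumes(bold: BoldSeries, n: int) -> BoldSeries:
    """Drop the first ``n`` volumes (T1-equilibration transient)."""
    if not 0 <= n < bold.n_volumes:
        raise ValueError(f"cannot discard {n} of {bold.n_volumes} volumes")
    return BoldSeries(data=bold.data[..., n:], affine=bold.affine, tr_s=bold.tr_s)


def _standardized_tissue_matrix(bold: BoldSeries, mask: np.ndarray) -> np.ndarray:
    ts = bold.data[mask]                       # (v, t)
    ts = signal.detrend(ts, axis=1, type="linear")
    sd = ts.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return ts / sd


def compcor_components(
    bold: BoldSeries, wm_mask: np.ndarray, csf_mask: np.ndarray, k: int = 5
) -> np.ndarray:
    """Top-k principal component time courses of the pooled WM+CSF voxels.

    Each tissue voxel's series is linearly detrended and standardized, the
    two voxel sets are pooled into one matrix, and the leading ``k`` right
    singular vectors (ordered by singular value) are returned as
    unit-variance columns of shape ``(t, k)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if wm_mask.sum() == 0 or csf_mask.sum() == 0:
        raise ValueError("WM and CSF masks must be nonempty")
    if wm_mask.shape != bold.grid_shape or csf_mask.shape != bold.grid_shape:
        raise ValueError("tissue masks must share the BOLD grid")
    pooled = np.vstack([
        _standardized_tissue_matrix(bold, wm_mask),
        _standardized_tissue_matrix(bold, csf_mask),
    ])
    if pooled.shape[0] < k:
        raise ValueError(f"pooled tissue mask has {pooled.shape[0]} voxels < k={k}")
    # right singular vectors via the (t x t) Gram matrix — t << voxels here
    gram = pooled.T @ pooled
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1][:k]
    comps = evecs[:, order]                   # (t, k)
    sd = comps.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return comps / sd


def motion_regressors(motion: MotionTrace) -> np.ndarray:
    """The 12-parameter motion expansion: 6 parameters + backward differences."""
    p = motion.params
    d = np.diff(p, axis=0, prepend=p[:1])     # first row of differences = 0
    return np.hstack([p, d])


def framewise_displacement(
    motion: MotionTrace, thresholds: QcThresholds = QcThresholds()
) -> np.ndarray:
    """Composite per-volume displacement in mm.

    Sum of absolute translation increments plus rotation increments
    converted to arc length at ``rotation_radius_mm``.  First volume is 0.
    """
    d = np.diff(motion.params, axis=0, prepend=motion.params[:1])
    return np.abs(d[:, :3]).sum(axis=1) + thresholds.rotation_radius_mm * np.abs(d[:, 3:]).sum(axis=1)


def flag_bad_volumes(
    bold: BoldSeries,
    motion: MotionTrace,
    thresholds: QcThresholds = QcThresholds(),
) -> np.ndarray:
    """Volumes corrupted by motion or global-intensity spikes.

    A volume is bad iff its composite framewise displacement exceeds
    ``fd_mm`` or the z-score of its global-mean intensity change exceeds
    ``global_z`` in magnitude.  Returns sorted unique indices.
    """
    if motion.n_volumes != bold.n_volumes:
        raise ValueError("motion trace not aligned with BOLD volumes")
    fd = framewise_displacement(motion, thresholds)
    g = bold.data.reshape(-1, bold.n_volumes).mean(axis=0)
    dg = np.diff(g, prepend=g[:1])
    sd = dg.std()
    z = dg / sd if sd > 0 else np.zeros_like(dg)
    bad = (fd > thresholds.fd_mm) | (np.abs(z) > thresholds.global_z)
    return np.flatnonzero(bad)


def qc_exclusion(
    bad: np.ndarray,
    n_retained: int,
    motion: MotionTrace,
    thresholds: QcThresholds = QcThresholds(),
) -> QcReport:
    """Subject/condition exclusion: >30% bad volumes or any translation >3 mm."""
    if n_retained <= 0:
        raise ValueError("n_retained must be positive")
    frac = len(np.unique(np.asarray(bad, dtype=int))) / n_retained
    max_t = float(np.abs(motion.params[:, :3]).max()) if motion.n_volumes else 0.0
    max_r = float(np.abs(motion.params[:, 3:]).max()) if motion.n_volumes else 0.0
    reasons = []
    if frac > thresholds.bad_fraction_max:
        reasons.append(f"bad-volume fraction {frac:.3f} > {thresholds.bad_fraction_max}")
    if max_t > thresholds.max_translation_mm:
        reasons.append(f"max translation {max_t:.2f} mm > {thresholds.max_translation_mm} mm")
    return QcReport(
        bad_volume_fraction=frac,
        max_abs_translation_mm=max_t,
        max_abs_rotation_rad=max_r,
        excluded=bool(reasons),
        reason="; ".join(reasons),
    )


def build_nuisance(
    bold: BoldSeries,
    motion: MotionTrace,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    k: int = 5,
) -> NuisanceMatrix:
    """Assemble the 19-column nuisance design: 5 CompCor + 12 motion + trend + intercept."""
    if motion.n_volumes != bold.n_volumes:
        raise ValueError("motion trace not aligned with BOLD volumes")
    t = bold.n_volumes
    comp = compcor_components(bold, wm_mask, csf_mask, k=k)
    mot = motion_regressors(motion)
    trend = np.linspace(-1.0, 1.0, t)[:, None]
    intercept = np.ones((t, 1))
    cols = np.hstack([comp, mot, trend, intercept])
    labels = (
        [f"compcor_{i + 1}" for i in range(k)]
        + [f"motion_{i + 1}" for i in range(6)]
        + [f"motion_diff_{i + 1}" for i in range(6)]
        + ["trend", "intercept"]
    )
    return NuisanceMatrix(regressors=cols, labels=labels)


def _scrub_columns(bad: np.ndarray, t: int) -> np.ndarray:
    bad = np.unique(np.asarray(bad, dtype=int))
    if bad.size and (bad.min() < 0 or bad.max() >= t):
        raise ValueError("bad-volume index out of range")
    cols = np.zeros((t, bad.size))
    cols[bad, np.arange(bad.size)] = 1.0
    return cols


def clean_timeseries(
    bold: BoldSeries,
    nuisance: NuisanceMatrix,
    bad: np.ndarray | None = None,
    band: tuple[float, float] | None = (0.01, 0.1),
    filter_order: int = 2,
    scrub_mode: str = "regress",
) -> BoldSeries:
    """Nuisance regression + scrubbing + band-pass, per voxel.

    One simultaneous OLS regression per voxel on the nuisance design
    augmented with a one-hot column per flagged volume, then residuals are
    band-pass filtered with a zero-phase Butterworth of the given order.
    ``band=None`` skips the filter and returns the raw regression
    residuals.  ``scrub_mode='delete'`` instead removes flagged volumes
    after regression (no indicator columns), at the cost of uneven
    temporal spacing.
    """
    if band is not None:
        f_lo, f_hi = band
        nyq = 0.5 / bold.tr_s
        if not 0 < f_lo < f_hi < nyq:
            raise ValueError(f"band ({f_lo}, {f_hi}) must lie below Nyquist {nyq}")
    t = bold.n_volumes
    if nuisance.regressors.shape[0] != t:
        raise ValueError("nuisance rows must match retained volumes")
    bad = np.asarray([] if bad is None else bad, dtype=int)

    X = nuisance.regressors
    if scrub_mode == "regress" and bad.size:
        X = np.hstack([X, _scrub_columns(bad, t)])
    elif scrub_mode not in ("regress", "delete"):
        raise ValueError("scrub_mode must be 'regress' or 'delete'")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("nuisance design is rank-deficient after scrub augmentation")

    Y = bold.data.reshape(-1, t).T            # (t, v)
    beta = np.linalg.solve(X.T @ X, X.T @ Y)
    resid = Y - X @ beta

    if scrub_mode == "delete" and bad.size:
        keep = np.setdiff1d(np.arange(t), bad)
        resid = resid[keep]
        t = keep.size

    if band is not None:
        sos = signal.butter(filter_order, (f_lo, f_hi), btype="bandpass",
                            fs=1.0 / bold.tr_s, output="sos")
        resid = signal.sosfiltfilt(sos, resid, axis=0)
    out = resid.T.reshape(bold.grid_shape + (t,))
    return BoldSeries(data=np.ascontiguousarray(out), affine=bold.affine, tr_s=bold.tr_s)


def smooth_map(map3d: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Gaussian-smooth a derived 3D map; ``fwhm_mm=0`` is the identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return map3d
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    return ndimage.gaussian_filter(np.asarray(map3d, dtype=float), sigma=sigma_vox)
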