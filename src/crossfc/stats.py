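"""Group-level inference for the 2x2 crossover design.

Three layers:

* one-sample validation maps (gFCD > 1, Fisher-z != 0) with either
  Benjamini-Hochberg FDR or max-statistic sign-flip permutation FWE at the
  voxel level;
* the time-by-drug interaction, operationalized as the per-subject
  difference of differences ``(verum_RS1 - verum_RS0) - (placebo_RS1 -
  placebo_RS0)`` regressed voxel-wise on an intercept plus mean-centered
  age and sequence covariates — the intercept t (df = n - 3) is the
  covariate-adjusted interaction statistic, equivalent to the classical
  repeated-measures interaction F (= t^2) when covariates are absent;
* cluster-level familywise-error control by sign-flipping permutation of
  the subject contrast maps: voxels above the two-sided height threshold
  (p < 0.001) form 18-connected clusters, and each observed cluster's size
  is referred to the permutation distribution of the maximum cluster size.

Post hoc paired t-tests compare cluster-mean connectivity between drugs at
each session and between sessions within each drug (df = n - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .simdata import DRUGS, SESSIONS

__all__ = [
    "OneSampleResult",
    "InteractionResult",
    "ClusterResult",
    "ClusterFweResult",
    "validate_design",
    "one_sample_map",
    "subject_contrast_maps",
    "covariate_matrix",
    "interaction_contrast",
    "cluster_fwe",
    "uncorrected_clusters",
    "posthoc_cluster_tests",
    "paired_t",
]

_CELLS = [(d, s) for d in DRUGS for s in SESSIONS]
_TINY_P = 5e-324          # smallest subnormal double: "p below machine floor"


# ---------------------------------------------------------------------------
# design handling

def validate_design(design: pd.DataFrame, require_paths: bool = False) -> pd.DataFrame:
    """Check the crossover design table: 4 cells per subject, consistent metadata."""
    required = {"subject", "sequence", "drug", "session", "age"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    problems = []
    for sid, grp in design.groupby("subject"):
        cells = set(zip(grp["drug"], grp["session"]))
        for cell in _CELLS:
            if cell not in cells:
                problems.append(f"subject {sid} missing cell {cell}")
        if len(grp) != 4:
            problems.append(f"subject {sid} has {len(grp)} rows, expected 4")
        if grp["sequence"].nunique() != 1:
            problems.append(f"subject {sid} has inconsistent sequence labels")
        if (grp["age"] <= 0).any():
            problems.append(f"subject {sid} has non-positive age")
    if require_paths and "bold_path" in design.columns:
        empty = design["bold_path"] == ""
        if empty.any():
            problems.append("design rows with empty bold_path")
    if problems:
        raise ValueError("invalid design table: " + "; ".join(problems))
    return design


# ---------------------------------------------------------------------------
# voxel-wise OLS machinery

def _ols_tmap(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """Intercept t-statistic of OLS per column of Y; df = n - p.

    Zero-residual-variance columns yield t = +-inf for a nonzero intercept
    and 0 for a zero one.
    """
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    c00 = np.linalg.inv(X.T @ X)[0, 0]
    beta = pinv @ Y
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(sigma2 * c00)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[0] / se
    t[np.isnan(t)] = 0.0
    return t, df


@dataclass
class OneSampleResult:
    t_map: np.ndarray
    p_map: np.ndarray
    sig_mask: np.ndarray
    df: int
    correction: str
    alpha: float


def one_sample_map(
    maps: np.ndarray,
    null_value: float = 0.0,
    correction: str = "fdr",
    alpha: float = 0.05,
    mask: np.ndarray | None = None,
    n_permutations: int = 2000,
    rng_seed: int = 0,
    tail: str = "two-sided",
) -> OneSampleResult:
    """Voxel-wise one-sample t-test of stacked subject maps against a null value.

    ``correction='fdr'`` applies Benjamini-Hochberg at ``alpha``;
    ``'voxel_fwe'`` uses the max-statistic sign-flipping permutation
    distribution.  ``tail='greater'`` tests exceedance only (used for hub
    maps, where only gFCD above the global mean is of interest).  Voxels
    with zero across-subject variance are masked out with a warning.
    """
    if tail not in ("two-sided", "greater"):
        raise ValueError("tail must be 'two-sided' or 'greater'")
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    vol_shape = maps.shape[1:]
    if mask is None:
        mask = np.ones(vol_shape, dtype=bool)
    Y = maps.reshape(n, -1)[:, mask.ravel()] - null_value

    sd = Y.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} voxels with zero across-subject variance masked out",
            stacklevel=2,
        )
    X = np.ones((n, 1))
    t, df = _ols_tmap(Y, X)
    t[degenerate] = 0.0
    if tail == "two-sided":
        p = 2.0 * sps.t.sf(np.abs(t), df)
    else:
        p = sps.t.sf(t, df)
    p[degenerate] = 1.0

    valid = ~degenerate
    sig = np.zeros(Y.shape[1], dtype=bool)
    if correction == "fdr":
        if valid.any():
            sig[valid] = multipletests(p[valid], alpha=alpha, method="fdr_bh")[0]
    elif correction == "voxel_fwe":
        rng = np.random.default_rng(rng_seed)
        maxstat = np.empty(n_permutations)
        stat = np.abs(t) if tail == "two-sided" else t
        for i in range(n_permutations):
            s = rng.choice((-1.0, 1.0), size=n)
            tp, _ = _ols_tmap(s[:, None] * Y, X)
            tp[degenerate] = 0.0
            maxstat[i] = np.abs(tp).max() if tail == "two-sided" else tp.max()
        p_fwe = (1.0 + (maxstat[None, :] >= stat[:, None]).sum(axis=1)) / (1.0 + n_permutations)
        sig = valid & (p_fwe <= alpha)
    else:
        raise ValueError("correction must be 'fdr' or 'voxel_fwe'")

    def unflatten(vals, fill=0.0, dtype=float):
        out = np.full(vol_shape, fill, dtype=dtype)
        out.ravel()[mask.ravel()] = vals
        return out

    return OneSampleResult(
        t_map=unflatten(t), p_map=unflatten(p, fill=1.0),
        sig_mask=unflatten(sig, fill=False, dtype=bool),
        df=df, correction=correction, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# crossover contrasts

def subject_contrast_maps(
    design: pd.DataFrame,
    maps: dict,
    contrast: str = "interaction",
) -> tuple[list, np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject contrast maps over the 2x2 cells.

    ``maps`` maps ``(subject, drug, session)`` to a 3D array.  Subjects with
    a missing cell are dropped with a warning; fewer than 4 complete
    subjects is an error.  Returns (subjects, contrast maps stacked on axis
    0, ages, sequence indicators +-0.5).
    """
    weights = {
        "interaction": {("verum", "RS1"): 1, ("verum", "RS0"): -1,
                        ("placebo", "RS1"): -1, ("placebo", "RS0"): 1},
        "time": {("verum", "RS1"): 0.5, ("verum", "RS0"): -0.5,
                 ("placebo", "RS1"): 0.5, ("placebo", "RS0"): -0.5},
        "drug": {("verum", "RS1"): 0.5, ("verum", "RS0"): 0.5,
                 ("placebo", "RS1"): -0.5, ("placebo", "RS0"): -0.5},
    }
    if contrast not in weights:
        raise ValueError(f"unknown contrast '{contrast}'")
    w = weights[contrast]

    subjects, deltas, ages, seqs = [], [], [], []
    for sid, grp in design.drop_duplicates(["subject", "drug", "session"]).groupby("subject", sort=True):
        have = {cell: maps.get((sid, *cell)) for cell in _CELLS}
        if any(v is None for v in have.values()):
            warnings.warn(f"subject {sid} dropped: incomplete 2x2 cells", stacklevel=2)
            continue
        delta = sum(w[cell] * np.asarray(have[cell], dtype=float) for cell in _CELLS)
        subjects.append(sid)
        deltas.append(delta)
        ages.append(float(grp["age"].iloc[0]))
        seqs.append(0.5 if grp["sequence"].iloc[0] == "verum-first" else -0.5)
    if len(subjects) < 4:
        raise ValueError(f"only {len(subjects)} complete subjects; need >= 4")
    return subjects, np.stack(deltas), np.asarray(ages), np.asarray(seqs)


def covariate_matrix(ages: np.ndarray | None, sequences: np.ndarray | None) -> np.ndarray:
    """Design matrix [intercept, centered age, centered sequence indicator]."""
    if ages is None and sequences is None:
        raise ValueError("need at least one of ages/sequences, or build an intercept-only X directly")
    n = len(ages if ages is not None else sequences)
    cols = [np.ones(n)]
    if ages is not None:
        cols.append(np.asarray(ages, dtype=float) - np.mean(ages))
    if sequences is not None:
        seq = np.asarray(sequences, dtype=float)
        cols.append(seq - seq.mean())
    return np.column_stack(cols)


@dataclass
class InteractionResult:
    subjects: list
    delta_maps: np.ndarray      # (n, x, y, z)
    t_map: np.ndarray           # 3D
    df: int
    X: np.ndarray               # (n, p) covariate design
    contrast: str


def interaction_contrast(
    design: pd.DataFrame,
    maps: dict,
    contrast: str = "interaction",
    covariates: bool = True,
) -> InteractionResult:
    """Covariate-adjusted voxel-wise t-map of a within-subject contrast.

    With age + sequence covariates the intercept t has n - 3 degrees of
    freedom; without, n - 1.
    """
    subjects, delta, ages, seqs = subject_contrast_maps(design, maps, contrast)
    n = len(subjects)
    X = covariate_matrix(ages, seqs) if covariates else np.ones((n, 1))
    Y = delta.reshape(n, -1)
    t, df = _ols_tmap(Y, X)
    return InteractionResult(
        subjects=subjects, delta_maps=delta,
        t_map=t.reshape(delta.shape[1:]), df=df, X=X, contrast=contrast,
    )


# ---------------------------------------------------------------------------
# cluster-level permutation FWE

_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ClusterResult:
    label: int
    size: int
    peak_t: float
    peak_ijk: tuple[int, int, int]
    peak_mm: tuple[float, float, float] | None
    p_fwe: float
    sign: int                   # +1 positive-t cluster, -1 negative


@dataclass
class ClusterFweResult:
    clusters: list
    t_map: np.ndarray
    t_crit: float
    df: int
    n_permutations: int
    null_max_size: np.ndarray
    connectivity: int = 18

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p_fwe <= alpha]

    def cluster_mask(self, cluster: ClusterResult) -> np.ndarray:
        struct = _CONNECTIVITY_STRUCTS[self.connectivity]
        supra = self.t_map > self.t_crit if cluster.sign > 0 else self.t_map < -self.t_crit
        lab, _ = ndimage.label(supra, structure=struct)
        return lab == cluster.label


def _cluster_sizes(supra: np.ndarray, structure: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return labels, 0, np.zeros(0, dtype=int)
    sizes = np.bincount(labels.ravel())[1:]
    return labels, n, sizes


def cluster_fwe(
    delta_maps: np.ndarray,
    ages: np.ndarray | None = None,
    sequences: np.ndarray | None = None,
    height_p: float = 0.001,
    n_permutations: int = 1000,
    rng_seed: int = 0,
    connectivity: int = 18,
    affine: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> ClusterFweResult:
    """Cluster-level FWE by sign-flipping permutation of subject contrast maps.

    The observed t-map is thresholded two-sided at the Student quantile for
    ``height_p``; connected components (18-neighborhood by default) of each
    sign are clusters.  The null distribution of the maximum cluster size
    (over both signs) is built by flipping the sign of each subject's
    contrast map and recomputing the full t-map and labeling;
    ``p_fwe = (1 + #{perm max >= k}) / (1 + n_permutations)``.
    """
    if not 0.0 < height_p < 1.0:
        raise ValueError("height_p must be in (0, 1)")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = _CONNECTIVITY_STRUCTS[connectivity]

    delta_maps = np.asarray(delta_maps, dtype=float)
    n = delta_maps.shape[0]
    vol_shape = delta_maps.shape[1:]
    if mask is None:
        mask = np.ones(vol_shape, dtype=bool)
    flat_mask = mask.ravel()
    Y = delta_maps.reshape(n, -1)[:, flat_mask]

    if ages is None and sequences is None:
        X = np.ones((n, 1))
    else:
        X = covariate_matrix(ages, sequences)

    t_obs, df = _ols_tmap(Y, X)
    t_crit = float(sps.t.ppf(1.0 - height_p / 2.0, df))

    def to_vol(tvals):
        out = np.zeros(vol_shape)
        out.ravel()[flat_mask] = tvals
        return out

    t_vol = to_vol(t_obs)
    observed = []
    for sign, supra in ((1, t_vol > t_crit), (-1, t_vol < -t_crit)):
        labels, ncl, sizes = _cluster_sizes(supra & mask, structure)
        for lab in range(1, ncl + 1):
            in_cl = labels == lab
            tvals = t_vol[in_cl]
            peak_flat = np.argmax(np.abs(tvals))
            coords = np.argwhere(in_cl)
            peak_ijk = tuple(int(v) for v in coords[peak_flat])
            peak_mm = None
            if affine is not None:
                peak_mm = tuple(float(v) for v in (affine @ np.array(peak_ijk + (1,)))[:3])
            observed.append(ClusterResult(
                label=lab, size=int(sizes[lab - 1]), peak_t=float(tvals[peak_flat]),
                peak_ijk=peak_ijk, peak_mm=peak_mm, p_fwe=np.nan, sign=sign,
            ))

    rng = np.random.default_rng(rng_seed)
    null_max = np.zeros(n_permutations, dtype=int)
    for i in range(n_permutations):
        s = rng.choice((-1.0, 1.0), size=n)
        tp, _ = _ols_tmap(s[:, None] * Y, X)
        tp_vol = to_vol(tp)
        best = 0
        for supra in (tp_vol > t_crit, tp_vol < -t_crit):
            _, ncl, sizes = _cluster_sizes(supra & mask, structure)
            if ncl:
                best = max(best, int(sizes.max()))
        null_max[i] = best

    for c in observed:
        c.p_fwe = float((1 + (null_max >= c.size).sum()) / (1 + n_permutations))
    observed.sort(key=lambda c: (-c.size, -abs(c.peak_t)))
    return ClusterFweResult(
        clusters=observed, t_map=t_vol, t_crit=t_crit, df=df,
        n_permutations=n_permutations, null_max_size=null_max,
        connectivity=connectivity,
    )


def uncorrected_clusters(
    t_map: np.ndarray,
    df: int,
    height_p: float = 0.005,
    min_extent: int = 10,
    connectivity: int = 18,
    affine: np.ndarray | None = None,
) -> list:
    """Exploratory thresholding without familywise-error control.

    Two-sided height threshold (default p < 0.005) plus a minimum cluster
    extent (default > 10 voxels); no permutation null, so ``p_fwe`` is NaN.
    For descriptive maps only — not a substitute for :func:`cluster_fwe`.
    """
    structure = _CONNECTIVITY_STRUCTS[connectivity]
    t_crit = float(sps.t.ppf(1.0 - height_p / 2.0, df))
    out = []
    for sign, supra in ((1, t_map > t_crit), (-1, t_map < -t_crit)):
        labels, ncl, sizes = _cluster_sizes(supra, structure)
        for lab in range(1, ncl + 1):
            if sizes[lab - 1] <= min_extent:
                continue
            in_cl = labels == lab
            tvals = t_map[in_cl]
            peak = np.argmax(np.abs(tvals))
            ijk = tuple(int(v) for v in np.argwhere(in_cl)[peak])
            mm = None
            if affine is not None:
                mm = tuple(float(v) for v in (affine @ np.array(ijk + (1,)))[:3])
            out.append(ClusterResult(label=lab, size=int(sizes[lab - 1]),
                                     peak_t=float(tvals[peak]), peak_ijk=ijk,
                                     peak_mm=mm, p_fwe=float("nan"), sign=sign))
    out.sort(key=lambda c: (-c.size, -abs(c.peak_t)))
    return out


# ---------------------------------------------------------------------------
# post hoc paired tests

def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Two-sided paired t; degenerate zero-variance differences handled.

    A constant nonzero difference gives t = +-inf with p reported at the
    subnormal floor; identical vectors give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need paired vectors of equal length >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        return float(np.sign(d.mean()) * np.inf), n - 1, _TINY_P
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def posthoc_cluster_tests(
    design: pd.DataFrame,
    maps: dict,
    cluster_mask: np.ndarray,
) -> pd.DataFrame:
    """Paired t-tests on cluster-mean values across the 2x2 cells.

    Compares verum vs placebo at each session and RS1 vs RS0 within each
    drug, on the cluster-mean map values of the subjects with complete
    cells.  (The cluster is selected by a prior interaction test, so these
    are descriptive follow-ups, not independent confirmation.)
    """
    if not cluster_mask.any():
        raise ValueError("cluster mask is empty")
    cell_values: dict = {cell: [] for cell in _CELLS}
    for sid in sorted(design["subject"].unique()):
        vals = {}
        for cell in _CELLS:
            m = maps.get((sid, *cell))
            if m is None:
                break
            vals[cell] = float(np.asarray(m)[cluster_mask].mean())
        else:
            for cell, v in vals.items():
                cell_values[cell].append(v)
    n = len(cell_values[_CELLS[0]])
    if n < 2:
        raise ValueError("need at least 2 complete subjects")
    cv = {cell: np.asarray(v) for cell, v in cell_values.items()}

    comparisons = [
        ("verum_vs_placebo_RS0", cv[("verum", "RS0")], cv[("placebo", "RS0")]),
        ("verum_vs_placebo_RS1", cv[("verum", "RS1")], cv[("placebo", "RS1")]),
        ("RS1_vs_RS0_placebo", cv[("placebo", "RS1")], cv[("placebo", "RS0")]),
        ("RS1_vs_RS0_verum", cv[("verum", "RS1")], cv[("verum", "RS0")]),
    ]
    rows = []
    for name, a, b in comparisons:
        t, df, p = paired_t(a, b)
        rows.append({"comparison": name, "t": t, "df": df, "p": p,
                     "mean_diff": float((a - b).mean()), "n": n})
    return pd.DataFrame(rows)
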