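"""Monte-Carlo experiments over synthetic cohorts.

Shared by the analysis drivers, the test suite and the acceptance script:
each function runs one self-contained replicate (generate -> preprocess ->
map -> infer) and returns the scalar outcome(s) the calibration or
recovery question asks about.  Problem sizes default to the reduced desk
scale used throughout (12^3 grid, 120 volumes, 20 subjects, 500
permutations); the full-cohort defaults of :mod:`crossfc.simdata` are not
changed here.
"""

from __future__ import annotations

import functools

import numpy as np

from . import preprocess as prep
from . import stats as cstats
from .config import PipelineConfig
from .gfcd import GfcdParams, compute_gfcd, gfcd_region_mean
from .pipeline import preprocess_session
from .seedfc import fc_region_mean, seed_fc_map
from .simdata import build_masks, default_config, generate_cohort

__all__ = [
    "small_config",
    "interaction_delta_for_effect_size",
    "cohort_zfc_maps",
    "null_interaction_replicate",
    "hub_recovery_replicate",
    "coupling_sign_replicate",
    "interaction_recovery_replicate",
]


def small_config(seed: int, n_subjects: int = 20, grid: int = 12,
                 n_volumes: int = 120, **overrides):
    """Reduced-scale cohort configuration for Monte-Carlo replicates."""
    return default_config(
        n_subjects=n_subjects, grid_shape=(grid,) * 3, n_volumes=n_volumes,
        rng_seed=int(seed) & 0x7FFFFFFF, **overrides,
    )


@functools.lru_cache(maxsize=8)
def _pilot_interaction_scaling(config, n_pilot: int = 24, pilot_seed: int = 990001):
    """Empirical null statistics of the per-voxel interaction contrast.

    Band-pass filtering reshapes both the noise level (raising the observed
    seed-voxel correlation) and the effective number of independent samples
    (inflating the Fisher-z sampling noise beyond 1/(T-3)), so the mapping
    from a latent coupling shift to an observed effect size is estimated
    from a pilot simulation under the null (``interaction_delta = 0``)
    rather than from a white-noise formula.  Returns ``(g_hat, sd_hat)``:
    the effective attenuation of the latent coupling in observed
    correlations, and the across-subject sd of the per-voxel interaction
    contrast at the target region (unsmoothed z).
    """
    cfg = config.replace(interaction_delta=0.0, n_subjects=n_pilot,
                         subject_coupling_sd=0.0, rng_seed=pilot_seed)
    cohort = generate_cohort(cfg)
    maps = cohort_zfc_maps(cohort, PipelineConfig(), smooth=False)
    target = cohort.truth.target_mask
    cells = {}
    for (sid, drug, sess), z in maps.items():
        cells.setdefault(sid, {})[(drug, sess)] = z[target]
    deltas, all_z = [], []
    for sid, c in cells.items():
        if len(c) == 4:
            deltas.append((c[("verum", "RS1")] - c[("verum", "RS0")])
                          - (c[("placebo", "RS1")] - c[("placebo", "RS0")]))
            all_z.extend(c.values())
    deltas = np.asarray(deltas)                 # (subjects, target voxels)
    sd_hat = float(deltas.std(axis=0, ddof=1).mean())
    mean_z = float(np.mean(all_z))
    g_hat = float(np.tanh(mean_z) / cfg.coupling_r)
    return g_hat, sd_hat


def interaction_delta_for_effect_size(d: float, config) -> float:
    """Latent coupling shift planting a per-voxel Cohen's d of ``d`` on the
    subject-level interaction contrast of unsmoothed Fisher-z values,
    using the pilot-estimated attenuation and contrast noise."""
    g, sd = _pilot_interaction_scaling(config.replace(rng_seed=0))
    r = config.coupling_r
    z0 = np.arctanh(g * r)
    z1 = z0 + np.sign(r) * d * sd
    return float(np.clip(np.tanh(z1) / g, -0.99, 0.99) - r)


def cohort_zfc_maps(cohort, pcfg: PipelineConfig, smooth: bool = True) -> dict:
    """Preprocess every session and return smoothed zFC maps keyed by cell."""
    masks = cohort.masks
    brain = masks.gm | masks.wm | masks.csf
    voxel = float(np.abs(np.diag(masks.affine)[:3]).mean())
    maps = {}
    for rec in cohort.sessions:
        cleaned, qc, _ = preprocess_session(rec.bold, rec.motion, masks, pcfg)
        if qc.excluded:
            continue
        fc = seed_fc_map(cleaned, masks.seed, brain)
        z = prep.smooth_map(fc.z, pcfg.fwhm_mm, voxel) if smooth else fc.z
        maps[(rec.subject, rec.drug, rec.session)] = z
    return maps


def _interaction_pieces(cohort, maps):
    design = cohort.design
    subjects, delta, ages, seqs = cstats.subject_contrast_maps(design, maps, "interaction")
    return subjects, delta, ages, seqs


def null_interaction_replicate(
    seed: int,
    n_subjects: int = 20,
    grid: int = 12,
    n_volumes: int = 120,
    n_permutations: int = 500,
    alpha: float = 0.05,
    pcfg: PipelineConfig | None = None,
) -> dict:
    """One null-cohort replicate: full pipeline, interaction T, cluster FWE.

    The cohort is null for the interaction (``interaction_delta = 0``,
    constant seed-target coupling) but keeps hubs, nuisance signals and
    motion spikes at their configured levels.  Returns the gray-matter
    T values, the interaction df, and whether any cluster reached
    ``p_fwe <= alpha``.
    """
    cfg = small_config(seed, n_subjects, grid, n_volumes, interaction_delta=0.0)
    cohort = generate_cohort(cfg)
    pcfg = pcfg or PipelineConfig(n_permutations=n_permutations,
                                  rng_seed=(int(seed) * 7919 + 11) & 0x7FFFFFFF)
    maps = cohort_zfc_maps(cohort, pcfg)
    subjects, delta, ages, seqs = _interaction_pieces(cohort, maps)
    res = cstats.cluster_fwe(
        delta, ages=ages, sequences=seqs, height_p=pcfg.height_p,
        n_permutations=n_permutations, rng_seed=pcfg.rng_seed,
        connectivity=pcfg.connectivity, mask=cohort.masks.gm,
    )
    min_p = min((c.p_fwe for c in res.clusters), default=1.0)
    return {
        "t_values": res.t_map[cohort.masks.gm],
        "df": res.df,
        "any_significant": min_p <= alpha,
        "min_p_fwe": min_p,
    }


def hub_recovery_replicate(seed: int, grid: int = 12, n_volumes: int = 120,
                           pcfg: PipelineConfig | None = None) -> dict:
    """One session with a planted hub community: is hub-region mean K/K0
    above the non-hub gray-matter background mean?"""
    cfg = small_config(seed, n_subjects=1, grid=grid, n_volumes=n_volumes)
    masks = build_masks(cfg)
    pcfg = pcfg or PipelineConfig()
    from .simdata import generate_session
    bold, motion, truth = generate_session(cfg, 0, "placebo", "RS0")
    cleaned, _, _ = preprocess_session(bold, motion, masks, pcfg)
    gmap = compute_gfcd(cleaned, masks.gm, GfcdParams(r_threshold=pcfg.gfcd_threshold))
    voxel = cfg.voxel_size_mm
    smoothed = prep.smooth_map(gmap.K_norm, pcfg.fwhm_mm, voxel)
    hub = truth.hub_mask
    background = masks.gm & ~hub
    hub_mean = gfcd_region_mean(smoothed, hub, masks.gm)
    bg_mean = gfcd_region_mean(smoothed, background, masks.gm)
    return {"hub_mean": hub_mean, "background_mean": bg_mean,
            "recovered": hub_mean > bg_mean}


def coupling_sign_replicate(seed: int, grid: int = 12, n_volumes: int = 120,
                            coupling_r: float = -0.5,
                            pcfg: PipelineConfig | None = None) -> dict:
    """One session with planted negative seed-target coupling: sign of the
    smoothed target-region mean Fisher z."""
    cfg = small_config(seed, n_subjects=1, grid=grid, n_volumes=n_volumes,
                       coupling_r=coupling_r, interaction_delta=0.0)
    masks = build_masks(cfg)
    pcfg = pcfg or PipelineConfig()
    from .simdata import generate_session
    bold, motion, truth = generate_session(cfg, 0, "placebo", "RS0")
    cleaned, _, _ = preprocess_session(bold, motion, masks, pcfg)
    fc = seed_fc_map(cleaned, masks.seed, masks.gm | masks.wm | masks.csf)
    z_sm = prep.smooth_map(fc.z, pcfg.fwhm_mm, cfg.voxel_size_mm)
    mean_z = fc_region_mean(z_sm, truth.target_mask)
    return {"target_mean_z": mean_z, "negative": mean_z < 0}


def interaction_recovery_replicate(
    seed: int,
    n_subjects: int = 35,
    grid: int = 12,
    n_volumes: int = 120,
    n_permutations: int = 500,
    effect_size_d: float = 1.0,
    alpha: float = 0.05,
) -> dict:
    """One cohort with a planted time-by-drug interaction on the seed-target
    coupling, sized to a per-voxel Cohen's d of ``effect_size_d`` on the
    subject contrast.  Detection = a significant cluster of the planted
    sign overlapping the target region."""
    base = small_config(seed, n_subjects, grid, n_volumes)
    delta = interaction_delta_for_effect_size(effect_size_d, base)
    cfg = base.replace(interaction_delta=delta)
    cohort = generate_cohort(cfg)
    pcfg = PipelineConfig(n_permutations=n_permutations,
                          rng_seed=(int(seed) * 6311 + 5) & 0x7FFFFFFF)
    maps = cohort_zfc_maps(cohort, pcfg)
    subjects, dmaps, ages, seqs = _interaction_pieces(cohort, maps)
    res = cstats.cluster_fwe(
        dmaps, ages=ages, sequences=seqs, height_p=pcfg.height_p,
        n_permutations=n_permutations, rng_seed=pcfg.rng_seed,
        connectivity=pcfg.connectivity, mask=cohort.masks.gm,
    )
    planted_sign = int(np.sign(delta))
    target = cohort.truth.target_mask
    detected = False
    for c in res.significant(alpha):
        if c.sign == planted_sign and (res.cluster_mask(c) & target).any():
            detected = True
            break
    return {"planted_delta": delta, "detected": detected,
            "n_significant": len(res.significant(alpha))}
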