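"""End-to-end orchestration: QC -> clean -> per-session maps -> group stats.

Per session: discard initial volumes, build the nuisance design (CompCor +
motion + trend), flag and scrub bad volumes, apply QC exclusion rules,
band-pass, then compute the smoothed gFCD (K/K0) and seed Fisher-z maps.
A subject is dropped from the group stage if any of its four sessions
fails QC (matching the per-participant exclusion logic of the emulated
trial).  Group stage: one-sample hub map (gFCD > 1, voxel FWE), one-sample
seed-FC map (z != 0, FDR), the covariate-adjusted time-by-drug interaction
with permutation cluster FWE, and post hoc paired tests on each
significant cluster's mean connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import preprocess as prep
from . import stats as cstats
from .config import PipelineConfig
from .gfcd import GfcdParams, compute_gfcd
from .seedfc import seed_fc_map
from .simdata import BoldSeries, Cohort, MaskSet, MotionTrace

log = logging.getLogger("crossfc")

__all__ = ["SessionOutput", "PipelineOutputs", "preprocess_session", "session_maps",
           "run_cohort", "run_pipeline"]


@dataclass
class SessionOutput:
    subject: str
    drug: str
    session: str
    qc: prep.QcReport
    bad_volumes: np.ndarray
    gfcd_norm_smoothed: np.ndarray | None = None
    zfc_smoothed: np.ndarray | None = None


@dataclass
class PipelineOutputs:
    sessions: list
    qc_table: pd.DataFrame
    excluded_subjects: list
    hub_one_sample: "cstats.OneSampleResult | None"
    fc_one_sample: "cstats.OneSampleResult | None"
    interaction: "cstats.InteractionResult | None"
    clusters: "cstats.ClusterFweResult | None"
    posthoc: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def preprocess_session(
    bold: BoldSeries,
    motion: MotionTrace,
    masks: MaskSet,
    cfg: PipelineConfig,
) -> tuple[BoldSeries, prep.QcReport, np.ndarray]:
    """Discard, QC, nuisance-regress + scrub + band-pass one session."""
    cio.check_same_grid(bold, masks.gm, "bold", "gm mask")
    if motion.n_volumes != bold.n_volumes:
        raise ValueError("motion trace rows must equal BOLD volumes before discarding")
    thresholds = prep.QcThresholds(
        fd_mm=cfg.fd_threshold_mm, global_z=cfg.global_z_threshold,
        bad_fraction_max=cfg.bad_fraction_max,
        max_translation_mm=cfg.max_translation_mm,
    )
    bold = prep.discard_initial_volumes(bold, cfg.n_discard)
    motion = motion.trimmed(cfg.n_discard)
    bad = prep.flag_bad_volumes(bold, motion, thresholds)
    qc = prep.qc_exclusion(bad, bold.n_volumes, motion, thresholds)
    nuis = prep.build_nuisance(bold, motion, masks.wm, masks.csf, k=cfg.compcor_k)
    cleaned = prep.clean_timeseries(
        bold, nuis, bad=bad, band=cfg.band_hz,
        filter_order=cfg.filter_order, scrub_mode=cfg.scrub_mode,
    )
    return cleaned, qc, bad


def session_maps(cleaned: BoldSeries, masks: MaskSet, cfg: PipelineConfig) -> dict:
    """Smoothed derived maps for one cleaned session."""
    gmap = compute_gfcd(cleaned, masks.gm, GfcdParams(r_threshold=cfg.gfcd_threshold))
    voxel = float(np.abs(np.diag(masks.affine)[:3]).mean())
    gfcd_sm = prep.smooth_map(gmap.K_norm, cfg.fwhm_mm, voxel)
    brain = masks.gm | masks.wm | masks.csf
    fc = seed_fc_map(cleaned, masks.seed, brain)
    zfc_sm = prep.smooth_map(fc.z, cfg.fwhm_mm, voxel)
    return {"gfcd": gmap, "gfcd_norm_smoothed": gfcd_sm, "zfc": fc,
            "zfc_smoothed": zfc_sm}


def _first_period_drug(sequence: str) -> str:
    return "verum" if sequence == "verum-first" else "placebo"


def run_cohort(cohort: Cohort, cfg: PipelineConfig) -> PipelineOutputs:
    """Run the full analysis on an in-memory cohort."""
    masks = cohort.masks
    outputs: list[SessionOutput] = []
    qc_rows = []
    excluded = set()

    for rec in cohort.sessions:
        bold = rec.bold if rec.bold is not None else cio.read_bold(rec.bold_path)
        motion = rec.motion if rec.motion is not None else cio.read_motion(rec.motion_path)
        cleaned, qc, bad = preprocess_session(bold, motion, masks, cfg)
        out = SessionOutput(subject=rec.subject, drug=rec.drug, session=rec.session,
                            qc=qc, bad_volumes=bad)
        if qc.excluded:
            excluded.add(rec.subject)
            log.info("excluding %s (%s/%s): %s", rec.subject, rec.drug, rec.session, qc.reason)
        else:
            m = session_maps(cleaned, masks, cfg)
            out.gfcd_norm_smoothed = m["gfcd_norm_smoothed"]
            out.zfc_smoothed = m["zfc_smoothed"]
        outputs.append(out)
        qc_rows.append({
            "subject": rec.subject, "drug": rec.drug, "session": rec.session,
            "bad_fraction": qc.bad_volume_fraction,
            "max_translation_mm": qc.max_abs_translation_mm,
            "excluded": qc.excluded, "reason": qc.reason,
        })

    qc_table = pd.DataFrame(qc_rows)
    design = cohort.design[~cohort.design["subject"].isin(excluded)].reset_index(drop=True)
    kept = sorted(design["subject"].unique())
    zfc_maps = {(o.subject, o.drug, o.session): o.zfc_smoothed
                for o in outputs if o.subject in kept and o.zfc_smoothed is not None}
    gfcd_maps = {(o.subject, o.drug, o.session): o.gfcd_norm_smoothed
                 for o in outputs if o.subject in kept and o.gfcd_norm_smoothed is not None}

    hub_os = fc_os = inter = clusters = None
    posthoc = None
    if len(kept) >= 4:
        # validation maps on each subject's first-period pre-dose session
        seq = {s: design.loc[design.subject == s, "sequence"].iloc[0] for s in kept}
        hub_stack = np.stack([gfcd_maps[(s, _first_period_drug(seq[s]), "RS0")] for s in kept])
        fc_stack = np.stack([zfc_maps[(s, _first_period_drug(seq[s]), "RS0")] for s in kept])
        hub_os = cstats.one_sample_map(hub_stack, null_value=1.0, correction="voxel_fwe",
                                       mask=masks.gm, n_permutations=min(cfg.n_permutations, 2000),
                                       rng_seed=cfg.rng_seed, tail="greater")
        brain = masks.gm | masks.wm | masks.csf
        fc_os = cstats.one_sample_map(fc_stack, null_value=0.0, correction="fdr", mask=brain)

        inter = cstats.interaction_contrast(design, zfc_maps, contrast="interaction")
        ages = np.array([design.loc[design.subject == s, "age"].iloc[0] for s in inter.subjects])
        seqs = np.array([0.5 if seq[s] == "verum-first" else -0.5 for s in inter.subjects])
        clusters = cstats.cluster_fwe(
            inter.delta_maps, ages=ages, sequences=seqs,
            height_p=cfg.height_p, n_permutations=cfg.n_permutations,
            rng_seed=cfg.rng_seed, connectivity=cfg.connectivity,
            affine=masks.affine, mask=masks.gm,
        )
        sig = clusters.significant(cfg.cluster_alpha)
        if sig:
            posthoc = pd.concat(
                [cstats.posthoc_cluster_tests(design, zfc_maps, clusters.cluster_mask(c))
                 .assign(cluster=i + 1, cluster_size=c.size, cluster_p_fwe=c.p_fwe)
                 for i, c in enumerate(sig)],
                ignore_index=True,
            )
    else:
        log.warning("only %d subjects pass QC; skipping group stage", len(kept))

    return PipelineOutputs(
        sessions=outputs, qc_table=qc_table, excluded_subjects=sorted(excluded),
        hub_one_sample=hub_os, fc_one_sample=fc_os, interaction=inter,
        clusters=clusters, posthoc=posthoc,
    )


def _cluster_table(result: "cstats.ClusterFweResult", contrast: str) -> pd.DataFrame:
    rows = []
    for c in result.clusters:
        mm = c.peak_mm if c.peak_mm is not None else (np.nan,) * 3
        rows.append({"contrast": contrast, "p_fwe": c.p_fwe, "k": c.size,
                     "T": c.peak_t, "x": mm[0], "y": mm[1], "z": mm[2],
                     "sign": c.sign})
    return pd.DataFrame(rows, columns=["contrast", "p_fwe", "k", "T", "x", "y", "z", "sign"])


def run_pipeline(cfg: PipelineConfig) -> PipelineOutputs:
    """File-based pipeline: read the cohort tree, run, write outputs + manifest."""
    root = Path(cfg.cohort_root)
    out_root = cio.ensure_dir(cfg.output_root)
    design = cio.read_design(root / "design.csv")
    masks = cio.read_masks(root)

    from .simdata import SessionRecord
    sessions = []
    for _, row in design.iterrows():
        bpath, mpath = Path(row["bold_path"]), Path(row["motion_path"])
        if not bpath.is_absolute():
            bpath = root / bpath
        if not mpath.is_absolute():
            mpath = root / mpath
        sessions.append(SessionRecord(
            subject=row["subject"], sequence=row["sequence"], drug=row["drug"],
            session=row["session"], age=float(row["age"]),
            bold_path=str(bpath), motion_path=str(mpath),
        ))
    cohort = Cohort(sessions=sessions, masks=masks, design=design, truth=None, config=None)
    res = run_cohort(cohort, cfg)

    # persist results
    files = []
    qc_path = out_root / "qc_report.tsv"
    cio.write_table(qc_path, res.qc_table)
    files.append(qc_path)
    for name, os_res in (("hub_one_sample", res.hub_one_sample),
                         ("fc_one_sample", res.fc_one_sample)):
        if os_res is None:
            continue
        p = cio.write_map(out_root / f"{name}_T.nii.gz", os_res.t_map, masks.affine)
        cio.write_sidecar(p, {"stage": name, "df": os_res.df,
                              "correction": os_res.correction, "config": cfg.to_dict()})
        files.append(p)
    if res.clusters is not None:
        p = cio.write_map(out_root / "interaction_T.nii.gz", res.clusters.t_map, masks.affine)
        cio.write_sidecar(p, {"stage": "interaction", "df": res.clusters.df,
                              "t_crit": res.clusters.t_crit, "config": cfg.to_dict()})
        files.append(p)
        ct_path = out_root / "clusters.tsv"
        cio.write_table(ct_path, _cluster_table(res.clusters, "time_x_drug"))
        files.append(ct_path)
        if cfg.uncorrected:
            unc = cstats.uncorrected_clusters(res.clusters.t_map, res.clusters.df,
                                              connectivity=cfg.connectivity,
                                              affine=masks.affine)
            rows = [{"contrast": "time_x_drug", "k": c.size, "T": c.peak_t,
                     "x": c.peak_mm[0], "y": c.peak_mm[1], "z": c.peak_mm[2],
                     "sign": c.sign} for c in unc]
            unc_path = out_root / "clusters_uncorrected.tsv"
            cio.write_table(unc_path, pd.DataFrame(
                rows, columns=["contrast", "k", "T", "x", "y", "z", "sign"]))
            files.append(unc_path)
    if res.posthoc is not None:
        ph_path = out_root / "posthoc.tsv"
        cio.write_table(ph_path, res.posthoc)
        files.append(ph_path)

    manifest = {
        "config": cfg.to_dict(),
        "excluded_subjects": res.excluded_subjects,
        "n_sessions": len(res.sessions),
        "files": {str(p.relative_to(out_root)): cio.file_checksum(p) for p in files},
    }
    import json
    with open(out_root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    res.manifest = manifest
    return res
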