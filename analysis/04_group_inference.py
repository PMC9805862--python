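"""Group stage: validation maps, time-by-drug interaction, post hoc tests.

Stacks the smoothed per-session maps from scratch/maps/, runs the
one-sample validation maps (gFCD > 1 with voxel FWE; Fisher z != 0 with
FDR), the covariate-adjusted difference-of-differences interaction with
sign-flip cluster FWE (height p < 0.001, alpha 0.05), and paired post hoc
tests on each significant cluster.  Tables land in results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from crossfc import io as cio
from crossfc import stats as cstats
from crossfc.config import PipelineConfig
from crossfc.pipeline import _cluster_table, _first_period_drug

ROOT = Path(__file__).resolve().parents[1]
SEED = 2024


def main(seed: int = SEED) -> None:
    cohort_dir = ROOT / "scratch" / "cohort"
    maps_dir = ROOT / "scratch" / "maps"
    design = cio.read_design(cohort_dir / "design.csv")
    masks = cio.read_masks(cohort_dir)
    cfg = PipelineConfig(n_permutations=2000, rng_seed=seed)

    zfc, gfcd = {}, {}
    for _, row in design.iterrows():
        tag = f"{row['subject']}_{row['drug']}_{row['session']}"
        key = (row["subject"], row["drug"], row["session"])
        zpath = maps_dir / f"{tag}_zfc.nii.gz"
        if zpath.exists():
            zfc[key], _ = cio.read_map(zpath)
            gfcd[key], _ = cio.read_map(maps_dir / f"{tag}_gfcd.nii.gz")
    subjects = sorted({s for s, _, _ in zfc
                       if sum(k[0] == s for k in zfc) == 4})
    design = design[design["subject"].isin(subjects)].reset_index(drop=True)
    seq = {s: design.loc[design.subject == s, "sequence"].iloc[0] for s in subjects}

    hub_stack = np.stack([gfcd[(s, _first_period_drug(seq[s]), "RS0")] for s in subjects])
    hub_os = cstats.one_sample_map(hub_stack, null_value=1.0, correction="voxel_fwe",
                                   mask=masks.gm, rng_seed=seed, tail="greater")
    fc_stack = np.stack([zfc[(s, _first_period_drug(seq[s]), "RS0")] for s in subjects])
    brain = masks.gm | masks.wm | masks.csf
    fc_os = cstats.one_sample_map(fc_stack, null_value=0.0, correction="fdr", mask=brain)
    print(f"hub map (gFCD>1, voxel FWE): {int(hub_os.sig_mask.sum())} significant voxels")
    print(f"seed-FC map (z!=0, FDR): {int(fc_os.sig_mask.sum())} significant voxels")

    inter = cstats.interaction_contrast(design, zfc)
    ages = np.array([design.loc[design.subject == s, "age"].iloc[0] for s in inter.subjects])
    seqs = np.array([0.5 if seq[s] == "verum-first" else -0.5 for s in inter.subjects])
    clusters = cstats.cluster_fwe(inter.delta_maps, ages=ages, sequences=seqs,
                                  height_p=cfg.height_p, n_permutations=cfg.n_permutations,
                                  rng_seed=seed, affine=masks.affine, mask=masks.gm)
    table = _cluster_table(clusters, "time_x_drug")
    cio.write_table(ROOT / "results" / "interaction_clusters.tsv", table.round(4))
    print(f"\ninteraction clusters (height p<{cfg.height_p}, {cfg.n_permutations} permutations):")
    print(table.round(3).to_string(index=False) if len(table) else "  none above threshold")

    sig = clusters.significant(cfg.cluster_alpha)
    if sig:
        posthoc = pd.concat(
            [cstats.posthoc_cluster_tests(design, zfc, clusters.cluster_mask(c))
             .assign(cluster=i + 1, cluster_p_fwe=c.p_fwe)
             for i, c in enumerate(sig)], ignore_index=True)
        cio.write_table(ROOT / "results" / "posthoc_tests.tsv", posthoc.round(5))
        print("\npost hoc paired tests on significant clusters:")
        print(posthoc.round(4).to_string(index=False))
        hit = any((clusters.cluster_mask(c) & masks.target).any() for c in sig)
        print(f"\nsignificant cluster overlaps planted target region: {hit}")
    else:
        print("\nno cluster survived FWE correction")


if __name__ == "__main__":
    import sys
    main(int(sys.argv[1]) if len(sys.argv) > 1 else SEED)
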