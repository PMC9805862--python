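"""Group inference: one-sample maps, crossover contrasts, permutation clusters."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats as sps

from crossfc import stats as cstats
from crossfc.stats import (
    cluster_fwe,
    interaction_contrast,
    one_sample_map,
    paired_t,
    posthoc_cluster_tests,
    subject_contrast_maps,
    validate_design,
)


def _design(n, ages=None, sequences=None):
    rows = []
    for i in range(n):
        sid = f"s{i:02d}"
        seq = (sequences[i] if sequences is not None
               else ("verum-first" if i % 2 == 0 else "placebo-first"))
        age = ages[i] if ages is not None else 40 + i
        for drug in ("placebo", "verum"):
            for sess in ("RS0", "RS1"):
                rows.append({"subject": sid, "sequence": seq, "drug": drug,
                             "session": sess, "age": age})
    return pd.DataFrame(rows)


def _cell_maps(design, values):
    """values: dict (subject, drug, session) -> scalar; maps are 1-voxel volumes."""
    return {k: np.full((1, 1, 1), v) for k, v in values.items()}


# ---------------------------------------------------------------------------
# design validation

def test_design_validation_reports_missing_cell():
    d = _design(4)
    broken = d[~((d.subject == "s01") & (d.drug == "verum") & (d.session == "RS1"))]
    with pytest.raises(ValueError, match=r"s01.*verum.*RS1"):
        validate_design(broken)


# ---------------------------------------------------------------------------
# one-sample maps

def test_constant_null_maps_yield_no_detections():
    maps = np.full((6, 3, 3, 3), 1.0)
    with pytest.warns(UserWarning, match="zero across-subject"):
        res = one_sample_map(maps, null_value=1.0, correction="fdr")
    assert not res.sig_mask.any()


def test_bh_step_up_rule_matches_hand_computation():
    # step-up on (0.001, 0.02, 0.03, 0.5) at q=0.05: 0.03 <= 3/4*0.05 -> 3 rejections
    from statsmodels.stats.multitest import multipletests
    rej, *_ = multipletests([0.001, 0.02, 0.03, 0.5], alpha=0.05, method="fdr_bh")
    np.testing.assert_array_equal(rej, [True, True, True, False])


def test_one_sample_power_on_planted_region():
    """delta/sigma = 2, n = 20: planted region found at FDR 0.05 with
    sensitivity > 0.8 averaged over 50 replicates."""
    n, shape = 20, (6, 6, 6)
    region = np.zeros(shape, bool)
    region[1:3, 1:3, 1:3] = True
    hits, total = 0, 0
    for rep in range(50):
        rng = np.random.default_rng([101, rep])
        maps = rng.standard_normal((n,) + shape)
        maps[:, region] += 2.0
        res = one_sample_map(maps, null_value=0.0, correction="fdr")
        hits += int((res.sig_mask & region).sum())
        total += int(region.sum())
    assert hits / total > 0.8


def test_one_sample_voxel_fwe_controls_null():
    rng = np.random.default_rng(5)
    maps = rng.standard_normal((12, 5, 5, 5))
    res = one_sample_map(maps, correction="voxel_fwe", n_permutations=500, rng_seed=9)
    assert res.sig_mask.sum() <= 2             # at most a stray voxel under the null


# ---------------------------------------------------------------------------
# interaction contrast

ANOVA_CELLS = {
    # 6 subjects, balanced sequences; hand-checkable numbers
    "s00": {("placebo", "RS0"): 0.10, ("placebo", "RS1"): 0.15,
            ("verum", "RS0"): 0.05, ("verum", "RS1"): -0.20},
    "s01": {("placebo", "RS0"): 0.00, ("placebo", "RS1"): 0.05,
            ("verum", "RS0"): 0.10, ("verum", "RS1"): -0.10},
    "s02": {("placebo", "RS0"): 0.20, ("placebo", "RS1"): 0.25,
            ("verum", "RS0"): 0.15, ("verum", "RS1"): 0.00},
    "s03": {("placebo", "RS0"): -0.05, ("placebo", "RS1"): 0.00,
            ("verum", "RS0"): 0.00, ("verum", "RS1"): -0.25},
    "s04": {("placebo", "RS0"): 0.10, ("placebo", "RS1"): 0.10,
            ("verum", "RS0"): 0.20, ("verum", "RS1"): 0.05},
    "s05": {("placebo", "RS0"): 0.05, ("placebo", "RS1"): 0.15,
            ("verum", "RS0"): 0.10, ("verum", "RS1"): -0.05},
}


def _anova_fixture():
    design = _design(6)
    values = {(sid, d, s): ANOVA_CELLS[sid][(d, s)]
              for sid in ANOVA_CELLS for (d, s) in ANOVA_CELLS[sid]}
    return design, _cell_maps(design, values)


def test_interaction_equals_classical_rm_anova_f():
    """Without covariates, the interaction t^2 equals the 2x2
    repeated-measures interaction F — checked against the closed form and
    against statsmodels AnovaRM."""
    design, maps = _anova_fixture()
    res = interaction_contrast(design, maps, covariates=False)
    t = float(res.t_map[0, 0, 0])

    # closed form: paired t on the per-subject difference of differences
    c = np.array([
        (ANOVA_CELLS[s][("verum", "RS1")] - ANOVA_CELLS[s][("verum", "RS0")])
        - (ANOVA_CELLS[s][("placebo", "RS1")] - ANOVA_CELLS[s][("placebo", "RS0")])
        for s in sorted(ANOVA_CELLS)
    ])
    f_hand = (c.mean() / (c.std(ddof=1) / np.sqrt(len(c)))) ** 2
    assert t ** 2 == pytest.approx(f_hand, abs=1e-8)

    from statsmodels.stats.anova import AnovaRM
    long = pd.DataFrame([
        {"subject": s, "drug": d, "session": ses, "y": ANOVA_CELLS[s][(d, ses)]}
        for s in ANOVA_CELLS for (d, ses) in ANOVA_CELLS[s]
    ])
    table = AnovaRM(long, depvar="y", subject="subject",
                    within=["drug", "session"]).fit().anova_table
    f_lib = float(table.loc["drug:session", "F Value"])
    assert t ** 2 == pytest.approx(f_lib, rel=1e-8)
    assert res.df == 5


def test_interaction_covariate_dfs_and_posthoc_df():
    design, maps = _anova_fixture()
    res = interaction_contrast(design, maps, covariates=True)
    assert res.df == 3                         # n=6 minus intercept/age/sequence
    # with 35 subjects the post hoc paired test carries 34 df
    rng = np.random.default_rng(0)
    t, df, p = paired_t(rng.standard_normal(35), rng.standard_normal(35))
    assert df == 34


def test_incomplete_subject_dropped_with_warning():
    design, maps = _anova_fixture()
    del maps[("s03", "verum", "RS1")]
    with pytest.warns(UserWarning, match="s03"):
        subjects, delta, ages, seqs = subject_contrast_maps(design, maps)
    assert "s03" not in subjects and len(subjects) == 5


def test_null_interaction_t_follows_student_t():
    """Gaussian null cell maps: voxel-wise covariate-adjusted T ~ t(n-3)."""
    n = 20
    shape = (8, 8, 8)
    design = _design(n)
    rng = np.random.default_rng(42)
    tvals = []
    for rep in range(4):
        maps = {(f"s{i:02d}", d, s): rng.standard_normal(shape)
                for i in range(n) for d in ("placebo", "verum") for s in ("RS0", "RS1")}
        res = interaction_contrast(design, maps, covariates=True)
        assert res.df == n - 3
        tvals.append(res.t_map.ravel())
    ks = sps.kstest(np.concatenate(tvals), "t", args=(n - 3,))
    assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# clusters

def test_hand_countable_cluster_sizes_18_connectivity():
    vol = np.zeros((6, 6, 6), bool)
    # 7-voxel blob including an edge-diagonal neighbor (18-connected)
    vol[1, 1, 1:4] = True
    vol[1, 2, 1:3] = True
    vol[2, 2, 2] = True
    vol[2, 1, 3] = True                        # edge-diagonal from (1,1,3)
    # separate 3-voxel blob
    vol[4, 4, 0:3] = True
    labels, n = ndimage.label(vol, structure=ndimage.generate_binary_structure(3, 2))
    sizes = sorted(np.bincount(labels.ravel())[1:], reverse=True)
    assert n == 2 and sizes == [7, 3]


def test_all_zero_maps_give_empty_cluster_list():
    delta = np.zeros((8, 4, 4, 4))
    res = cluster_fwe(delta, n_permutations=100, rng_seed=1)
    assert res.clusters == []


def test_planted_cluster_detected_and_sized():
    n = 16
    shape = (8, 8, 8)
    rng = np.random.default_rng(7)
    delta = rng.standard_normal((n,) + shape)
    blob = np.zeros(shape, bool); blob[2:5, 2:5, 2] = True
    delta[:, blob] -= 3.0                      # strong negative effect
    res = cluster_fwe(delta, n_permutations=300, rng_seed=3)
    sig = res.significant(0.05)
    assert len(sig) >= 1
    top = sig[0]
    assert top.sign == -1
    assert (res.cluster_mask(top) & blob).sum() >= 0.8 * blob.sum()
    assert top.p_fwe < 0.05


def test_sign_equivariance_and_determinism():
    rng = np.random.default_rng(11)
    delta = rng.standard_normal((10, 5, 5, 5))
    delta[:, 1:3, 1:3, 1:3] += 2.5
    ages = rng.uniform(31, 59, 10)
    seqs = np.array([0.5, -0.5] * 5)
    r1 = cluster_fwe(delta, ages, seqs, n_permutations=200, rng_seed=17)
    r2 = cluster_fwe(-delta, ages, seqs, n_permutations=200, rng_seed=17)
    np.testing.assert_allclose(r1.t_map, -r2.t_map, atol=1e-10)
    assert [(c.size, c.p_fwe, -c.sign) for c in r1.clusters] == \
           [(c.size, c.p_fwe, c.sign) for c in r2.clusters]
    r3 = cluster_fwe(delta, ages, seqs, n_permutations=200, rng_seed=17)
    np.testing.assert_array_equal(r1.null_max_size, r3.null_max_size)
    assert [(c.size, c.p_fwe) for c in r1.clusters] == [(c.size, c.p_fwe) for c in r3.clusters]


def test_cluster_peak_mm_uses_affine():
    rng = np.random.default_rng(2)
    delta = rng.standard_normal((12, 5, 5, 5)) * 0.1
    delta[:, 4, 4, 4] += 5.0
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    res = cluster_fwe(delta, n_permutations=100, rng_seed=0, affine=affine)
    assert res.clusters
    assert res.clusters[0].peak_mm == (12.0, 12.0, 12.0)


def test_uncorrected_exploratory_thresholding():
    """Exploratory mode keeps only clusters above the extent floor and
    assigns no FWE p-value."""
    df = 17
    t_crit = sps.t.ppf(1 - 0.005 / 2, df)
    t_map = np.zeros((10, 10, 10))
    t_map[1:4, 1:4, 1:3] = t_crit + 1          # 18 voxels, > 10
    t_map[7, 7, 1:6] = -(t_crit + 2)           # 5 voxels, <= 10 -> dropped
    out = cstats.uncorrected_clusters(t_map, df, height_p=0.005, min_extent=10)
    assert len(out) == 1
    assert out[0].size == 18 and out[0].sign == 1
    assert np.isnan(out[0].p_fwe)


# ---------------------------------------------------------------------------
# post hoc tests

def test_posthoc_degenerate_cases():
    t, df, p = paired_t(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
    assert (t, p) == (0.0, 1.0)
    x = np.array([0.3, 1.2, -0.5, 0.8])
    t, df, p = paired_t(x + 0.7, x)
    assert np.isinf(t) and t > 0 and p < 1e-300


def test_posthoc_detects_rs1_difference_only():
    """Planted verum-placebo difference at RS1 only: the RS1 comparison is
    significant in most replicates, the RS0 comparison stays at chance."""
    n = 15
    design = _design(n)
    mask = np.ones((1, 1, 1), bool)
    rs1_sig, rs0_sig = 0, 0
    reps = 50
    for rep in range(reps):
        rng = np.random.default_rng([55, rep])
        values = {}
        for i in range(n):
            sid = f"s{i:02d}"
            base = rng.normal(0, 0.3)
            values[(sid, "placebo", "RS0")] = base + rng.normal(0, 0.2)
            values[(sid, "verum", "RS0")] = base + rng.normal(0, 0.2)
            values[(sid, "placebo", "RS1")] = base + rng.normal(0, 0.2)
            values[(sid, "verum", "RS1")] = base - 0.35 + rng.normal(0, 0.2)
        table = posthoc_cluster_tests(design, _cell_maps(design, values), mask)
        pvals = table.set_index("comparison")["p"]
        rs1_sig += pvals["verum_vs_placebo_RS1"] < 0.05
        rs0_sig += pvals["verum_vs_placebo_RS0"] < 0.05
    assert rs1_sig / reps > 0.8
    assert rs0_sig / reps < 0.25


def test_posthoc_table_shape():
    design, maps = _anova_fixture()
    table = posthoc_cluster_tests(design, maps, np.ones((1, 1, 1), bool))
    assert set(table["comparison"]) == {
        "verum_vs_placebo_RS0", "verum_vs_placebo_RS1",
        "RS1_vs_RS0_placebo", "RS1_vs_RS0_verum",
    }
    assert (table["df"] == 5).all()
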