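"""Denoising chain: CompCor, motion expansion, scrubbing, filtering, smoothing."""

import numpy as np
import pytest
from scipy import ndimage

from crossfc import preprocess as prep
from crossfc.preprocess import (
    NuisanceMatrix,
    QcThresholds,
    clean_timeseries,
    compcor_components,
    discard_initial_volumes,
    flag_bad_volumes,
    motion_regressors,
    qc_exclusion,
    smooth_map,
)
from crossfc.simdata import MotionTrace, default_config, generate_session

from .conftest import make_bold


# ---------------------------------------------------------------------------
# volume discarding

def test_discard_zero_is_identity(rng):
    b = make_bold(rng.standard_normal((2, 2, 2, 30)))
    out = discard_initial_volumes(b, 0)
    np.testing.assert_array_equal(out.data, b.data)


def test_discard_five_of_355(rng):
    b = make_bold(rng.standard_normal((1, 1, 2, 355)))
    assert discard_initial_volumes(b, 5).n_volumes == 350


def test_discard_all_volumes_forbidden(rng):
    b = make_bold(rng.standard_normal((1, 1, 1, 5)))
    with pytest.raises(ValueError):
        discard_initial_volumes(b, 5)


# ---------------------------------------------------------------------------
# CompCor

def test_single_voxel_compcor_recovers_standardized_series(rng):
    t = 60
    series = rng.standard_normal(t)
    data = np.zeros((3, 1, 1, t))
    data[0, 0, 0] = series
    data[1, 0, 0] = series          # csf voxel carries the same signal
    data[2, 0, 0] = rng.standard_normal(t)
    b = make_bold(data)
    wm = np.zeros((3, 1, 1), bool); wm[0] = True
    csf = np.zeros((3, 1, 1), bool); csf[1] = True
    comp = compcor_components(b, wm, csf, k=1)[:, 0]
    from scipy.signal import detrend
    ref = detrend(series)
    ref = (ref - ref.mean()) / ref.std()
    r = np.corrcoef(comp, ref)[0, 1]
    assert abs(r) > 0.9999


def test_compcor_recovers_planted_rank1_tissue_signal(rng):
    t, v = 80, 20
    shared = rng.standard_normal(t)
    data = np.zeros((v, 1, 2, t))
    data[:, 0, 0] = shared + 0.01 * rng.standard_normal((v, t))
    data[:, 0, 1] = shared + 0.01 * rng.standard_normal((v, t))
    b = make_bold(data)
    wm = np.zeros((v, 1, 2), bool); wm[:, 0, 0] = True
    csf = np.zeros((v, 1, 2), bool); csf[:, 0, 1] = True
    comp = compcor_components(b, wm, csf, k=1)[:, 0]
    assert abs(np.corrcoef(comp, shared)[0, 1]) > 0.99


def test_compcor_component_count_and_variance(rng):
    cfg = default_config(n_volumes=100)
    bold, _, _ = generate_session(cfg, 0, "placebo", "RS0")
    from crossfc.simdata import build_masks
    masks = build_masks(cfg)
    comp = compcor_components(bold, masks.wm, masks.csf, k=5)
    assert comp.shape == (100, 5)
    np.testing.assert_allclose(comp.std(axis=0), 1.0, rtol=1e-6)


def test_compcor_mask_smaller_than_k_rejected(rng):
    b = make_bold(rng.standard_normal((2, 1, 1, 30)))
    wm = np.zeros((2, 1, 1), bool); wm[0] = True
    csf = np.zeros((2, 1, 1), bool); csf[1] = True
    with pytest.raises(ValueError):
        compcor_components(b, wm, csf, k=5)


# ---------------------------------------------------------------------------
# motion regressors

def test_motion_regressor_expansion():
    t = 20
    zero = motion_regressors(MotionTrace(np.zeros((t, 6))))
    assert zero.shape == (t, 12)
    assert not zero.any()

    step = np.zeros((t, 6)); step[10:, 0] = 1.0
    reg = motion_regressors(MotionTrace(step))
    expected_diff = np.zeros(t); expected_diff[10] = 1.0
    np.testing.assert_array_equal(reg[:, 6], expected_diff)

    const = motion_regressors(MotionTrace(np.full((t, 6), 0.7)))
    assert (const[:, :6] == 0.7).all()
    assert not const[:, 6:].any()


# ---------------------------------------------------------------------------
# scrubbing & QC

def test_motionless_constant_series_has_no_bad_volumes():
    t = 40
    b = make_bold(np.full((2, 2, 1, t), 3.0))
    bad = flag_bad_volumes(b, MotionTrace(np.zeros((t, 6))))
    assert bad.size == 0


def test_translation_jump_flags_exactly_post_jump_volume():
    t = 50
    b = make_bold(np.full((1, 1, 2, t), 1.0))
    params = np.zeros((t, 6))
    params[25:, 1] = 2.0                       # persistent 2 mm step
    bad = flag_bad_volumes(b, MotionTrace(params))
    np.testing.assert_array_equal(bad, [25])


def test_planted_spikes_are_flagged(small_cfg):
    cfg = small_cfg.replace(spike_rate=0.05)
    bold, motion, truth = generate_session(cfg, 1, "verum", "RS1")
    bad = flag_bad_volumes(bold, motion)
    planted = truth.bad_volumes[("1", "verum", "RS1")]
    assert set(planted).issubset(set(bad.tolist()))


def test_qc_exclusion_boundaries():
    t = 350
    quiet = MotionTrace(np.full((t, 6), 0.0))
    ok = qc_exclusion(np.arange(0), t, quiet)
    assert not ok.excluded

    at_30pct = qc_exclusion(np.arange(105), t, quiet)     # 105/350 = 0.30
    assert not at_30pct.excluded
    over_30pct = qc_exclusion(np.arange(106), t, quiet)   # 106/350 > 0.30
    assert over_30pct.excluded and "fraction" in over_30pct.reason

    m3 = np.zeros((t, 6)); m3[5, 2] = 3.0
    assert not qc_exclusion(np.arange(0), t, MotionTrace(m3)).excluded
    m31 = np.zeros((t, 6)); m31[5, 2] = 3.1
    rep = qc_exclusion(np.arange(0), t, MotionTrace(m31))
    assert rep.excluded and "translation" in rep.reason


# ---------------------------------------------------------------------------
# nuisance regression + filtering

def _intercept_nuisance(t):
    return NuisanceMatrix(regressors=np.ones((t, 1)), labels=["intercept"])


def test_nuisance_design_has_19_columns(small_cfg):
    from crossfc.simdata import build_masks
    bold, motion, _ = generate_session(small_cfg, 0, "placebo", "RS0")
    masks = build_masks(small_cfg)
    nuis = prep.build_nuisance(bold, motion, masks.wm, masks.csf, k=5)
    assert nuis.regressors.shape == (bold.n_volumes, 19)
    assert nuis.labels[-1] == "intercept"


def test_residuals_orthogonal_to_nuisance(rng, small_cfg):
    from crossfc.simdata import build_masks
    bold, motion, _ = generate_session(small_cfg, 0, "placebo", "RS0")
    masks = build_masks(small_cfg)
    nuis = prep.build_nuisance(bold, motion, masks.wm, masks.csf)
    cleaned = clean_timeseries(bold, nuis, bad=[3, 17], band=None)
    resid = cleaned.data.reshape(-1, cleaned.n_volumes).T
    X = nuis.regressors
    dots = np.abs(X.T @ resid)
    bound = 1e-8 * np.linalg.norm(X, axis=0)[:, None] * np.linalg.norm(resid, axis=0)[None, :]
    assert (dots <= np.maximum(bound, 1e-10)).all()


def test_scrubbed_volumes_insensitive_to_raw_perturbation(rng, small_cfg):
    from crossfc.simdata import build_masks
    bold, motion, _ = generate_session(small_cfg, 0, "placebo", "RS0")
    masks = build_masks(small_cfg)
    nuis = prep.build_nuisance(bold, motion, masks.wm, masks.csf)
    bad = [10, 40, 41]
    base = clean_timeseries(bold, nuis, bad=bad, band=None)
    perturbed = bold.data.copy()
    perturbed[..., bad] += rng.standard_normal(perturbed[..., bad].shape) * 50
    from crossfc.simdata import BoldSeries
    b2 = BoldSeries(data=perturbed, affine=bold.affine, tr_s=bold.tr_s)
    out2 = clean_timeseries(b2, nuis, bad=bad, band=None)
    np.testing.assert_allclose(base.data, out2.data, atol=1e-8)


def test_scrub_by_deletion_removes_volumes(small_cfg):
    from crossfc.simdata import build_masks
    bold, motion, _ = generate_session(small_cfg, 0, "placebo", "RS0")
    masks = build_masks(small_cfg)
    nuis = prep.build_nuisance(bold, motion, masks.wm, masks.csf)
    out = clean_timeseries(bold, nuis, bad=[1, 2, 3], band=None, scrub_mode="delete")
    assert out.n_volumes == bold.n_volumes - 3


def _attenuation_db(freq_hz, t=350, tr=2.0):
    time = np.arange(t) * tr
    probe = np.sin(2 * np.pi * freq_hz * time)
    b = make_bold(probe, tr_s=tr)
    out = clean_timeseries(b, _intercept_nuisance(t), band=(0.01, 0.1))
    rms_in = np.sqrt((probe ** 2).mean())
    rms_out = np.sqrt((out.data.ravel() ** 2).mean())
    return 20 * np.log10(rms_out / rms_in)


def test_filter_stops_infraslow_drift():
    assert _attenuation_db(0.005) <= -20.0


def test_filter_passes_band_center():
    assert _attenuation_db(0.05) >= -1.0


def test_filter_attenuation_monotone_outside_band():
    lows = [_attenuation_db(f) for f in (0.002, 0.005, 0.008)]
    highs = [_attenuation_db(f) for f in (0.12, 0.17, 0.24)]
    assert lows == sorted(lows)
    assert highs == sorted(highs, reverse=True)


def test_band_above_nyquist_rejected(rng):
    b = make_bold(rng.standard_normal(50), tr_s=2.0)
    with pytest.raises(ValueError):
        clean_timeseries(b, _intercept_nuisance(50), band=(0.01, 0.3))


# ---------------------------------------------------------------------------
# smoothing

def test_smoothing_identity_and_mean_conservation(rng):
    m = rng.standard_normal((8, 8, 8))
    assert smooth_map(m, 0.0, 3.0) is m
    const = np.full((6, 6, 6), 2.5)
    np.testing.assert_allclose(smooth_map(const, 8.0, 3.0), 2.5)


def test_smoothing_matches_analytic_gaussian_kernel():
    fwhm, voxel = 8.0, 3.0
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / voxel
    n = 15
    impulse = np.zeros((n, n, n))
    impulse[n // 2, n // 2, n // 2] = 1.0
    out = smooth_map(impulse, fwhm, voxel)

    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k1 = np.exp(-x ** 2 / (2 * sigma ** 2))
    k1 /= k1.sum()
    expected = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    center = slice(n // 2 - radius, n // 2 + radius + 1)
    np.testing.assert_allclose(out[center, center, center], expected, atol=1e-6)
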