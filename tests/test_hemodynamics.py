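"""DSC/DCE quantification and the blood-voxel exclusion rules."""

import numpy as np
import pytest

from tizmap.hemodynamics import (
    dsc_to_delta_r2star, select_aif, leakage_correct, compute_cbv,
    normalize_cbv, vfa_t1_fit, dce_to_concentration, fit_extended_tofts,
    blood_exclusion_mask,
)
from tizmap.phantom import (
    PhantomSpec, gamma_variate, plasma_concentration, tofts_forward,
)
from scipy.integrate import cumulative_trapezoid


# ----------------------------------------------------------------- conversion

def test_constant_signal_gives_zero_delta_r2star():
    s = np.ones((20, 3, 3, 3))
    out = dsc_to_delta_r2star(s, te_ms=30.0, baseline_frames=5)
    assert np.allclose(out, 0.0)


def test_delta_r2star_inverts_definition():
    te = 30.0
    x = 7.5  # s^-1
    s = np.ones((10, 2, 2, 2))
    s[5:] = np.exp(-te / 1000.0 * x)
    out = dsc_to_delta_r2star(s, te, baseline_frames=5)
    assert np.allclose(out[5:], x, atol=1e-12)


def test_nonpositive_signal_flagged_as_zero():
    s = np.ones((10, 2, 2, 2))
    s[5, 0, 0, 0] = 0.0
    out = dsc_to_delta_r2star(s, 30.0, 3)
    assert out[5, 0, 0, 0] == 0.0
    assert np.isfinite(out).all()


def test_too_few_baseline_frames_rejected():
    with pytest.raises(ValueError):
        dsc_to_delta_r2star(np.ones((10, 2, 2, 2)), 30.0, 2)


# ------------------------------------------------------------------------ AIF

def _curves_volume(curves):
    """Stack 1D curves into a (n_frames, n, 1, 1) series with a full mask."""
    arr = np.stack(curves, axis=1)[:, :, None, None]
    mask = np.ones(arr.shape[1:], dtype=bool)
    return arr, mask


def test_single_voxel_aif_is_that_curve():
    t = np.arange(40.0)
    c = gamma_variate(t, 5, 3, 1.5, 40)
    series, mask = _curves_volume([c])
    assert np.allclose(select_aif(series, mask, k=5), c)


def test_aif_excludes_low_amplitude_outlier():
    t = np.arange(40.0)
    good = gamma_variate(t, 5, 3, 1.5, 40)
    outlier = gamma_variate(t, 5, 3, 1.5, 2)
    series, mask = _curves_volume([good] * 5 + [outlier])
    aif = select_aif(series, mask, k=5)
    assert np.allclose(aif, good)


def test_aif_empty_mask_raises():
    series = np.ones((10, 2, 2, 2))
    with pytest.raises(ValueError):
        select_aif(series, np.zeros((2, 2, 2), dtype=bool))


# -------------------------------------------------------------------- leakage

@pytest.fixture()
def dsc_setup():
    t = np.arange(120) * 1.5
    ca = gamma_variate(t, 20, 3, 1.5, 60)
    return t, ca


def test_leakage_identity_when_no_leak(dsc_setup):
    t, ca = dsc_setup
    ref_curve = 0.03 * ca
    curves = [ref_curve, 0.08 * ca]
    series, mask = _curves_volume(curves)
    ref_mask = np.zeros_like(mask)
    ref_mask[0] = True
    corrected, k2 = leakage_correct(series, ref_mask, t)
    assert np.abs(corrected - series).max() < 1e-9
    assert np.abs(k2).max() < 1e-12


def test_leakage_k2_recovered_within_5pct(dsc_setup):
    t, ca = dsc_setup
    ref_curve = 0.03 * ca
    int_ref = cumulative_trapezoid(ref_curve, t, initial=0.0)
    k2_true = 0.05
    leaky = 0.08 * ca - k2_true * int_ref
    series, mask = _curves_volume([ref_curve, leaky])
    ref_mask = np.zeros_like(mask)
    ref_mask[0] = True
    corrected, k2 = leakage_correct(series, ref_mask, t)
    assert k2[1, 0, 0] == pytest.approx(k2_true, rel=0.05)
    # corrected curve matches the leak-free curve
    assert np.abs(corrected[:, 1, 0, 0] - 0.08 * ca).max() < 0.05 * np.abs(0.08 * ca).max()


def test_reference_voxel_self_fit(dsc_setup):
    t, ca = dsc_setup
    ref_curve = 0.03 * ca
    series, mask = _curves_volume([ref_curve])
    corrected, k2 = leakage_correct(series, mask, t)
    assert abs(k2[0, 0, 0]) < 1e-12


# ------------------------------------------------------------------------ CBV

def test_cbv_ratio_properties(dsc_setup):
    t, ca = dsc_setup
    series, _ = _curves_volume([ca, 0.5 * ca])
    cbv = compute_cbv(series, ca, t)
    assert cbv[0, 0, 0] == pytest.approx(1.0)
    assert cbv[1, 0, 0] == pytest.approx(0.5)
    # joint rescale invariance
    cbv2 = compute_cbv(3.0 * series, 3.0 * ca, t)
    assert np.allclose(cbv2, cbv)


def test_normalize_cbv_median_one():
    rng = np.random.default_rng(0)
    cbv = rng.uniform(0.01, 0.08, (8, 8, 8))
    mask = np.zeros((8, 8, 8), dtype=bool)
    mask[:4] = True
    ncbv = normalize_cbv(cbv, mask)
    assert np.median(ncbv[mask]) == pytest.approx(1.0)
    assert normalize_cbv(ncbv, mask) == pytest.approx(ncbv)  # idempotent


def test_normalize_cbv_simple_ratio():
    cbv = np.full((2, 2, 2), 0.04)
    cbv[0, 0, 0] = 0.20
    mask = np.ones((2, 2, 2), dtype=bool)
    mask[0, 0, 0] = False
    assert normalize_cbv(cbv, mask)[0, 0, 0] == pytest.approx(5.0)


# ------------------------------------------------------------------------- T1

def _spgr(m0, t1_ms, tr_ms, fa_deg):
    e1 = np.exp(-tr_ms / t1_ms)
    a = np.deg2rad(fa_deg)
    return m0 * np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))


def test_vfa_exact_recovery():
    t1, m0, tr = 1000.0, 5.0, 5.0
    vols = [np.full((3, 3, 3), _spgr(m0, t1, tr, fa)) for fa in (5, 10, 15)]
    t1_est, m0_est, flags = vfa_t1_fit(vols, (5, 10, 15), tr)
    assert np.abs(t1_est - t1).max() < 0.1
    assert np.abs(m0_est - m0).max() < 1e-3
    assert not flags.any()


def test_vfa_nonphysical_slope_flagged():
    vols = [np.full((2, 2, 2), 1.0), np.full((2, 2, 2), 3.0),
            np.full((2, 2, 2), 9.0)]
    t1_est, _, flags = vfa_t1_fit(vols, (5, 10, 15), 5.0)
    assert flags.all()
    assert np.all(t1_est <= 10000.0)


def test_vfa_noisy_phantom_wm_error():
    rng = np.random.default_rng(1)
    t1, m0, tr = 800.0, 1.0, 5.0
    snr = 100.0
    vols = [np.full((16, 16, 16), _spgr(m0, t1, tr, fa))
            + rng.normal(0, _spgr(m0, t1, tr, 15) / snr, (16, 16, 16))
            for fa in (5, 10, 15)]
    t1_est, _, _ = vfa_t1_fit(vols, (5, 10, 15), tr)
    assert abs(np.median(t1_est) - t1) / t1 < 0.03


# -------------------------------------------------------------- concentration

def test_concentration_zero_at_baseline():
    t10 = np.full((2, 2, 2), 1000.0)
    s = np.full((30, 2, 2, 2), _spgr(1.0, 1000.0, 5.0, 15.0))
    conc = dce_to_concentration(s, t10, 15.0, 5.0, 3.6)
    assert np.abs(conc).max() < 1e-9


def test_concentration_round_trip_known_value():
    c_true, r1, t10 = 0.5, 3.6, 1200.0
    r1_t = 1000.0 / t10 + r1 * c_true
    s_base = _spgr(1.0, t10, 5.0, 15.0)
    s_enh = _spgr(1.0, 1000.0 / r1_t, 5.0, 15.0)
    s = np.full((20, 2, 2, 2), s_base)
    s[10:] = s_enh
    conc = dce_to_concentration(s, np.full((2, 2, 2), t10), 15.0, 5.0, r1)
    assert np.allclose(conc[10:], c_true, atol=1e-6)
    conc2 = dce_to_concentration(s, np.full((2, 2, 2), t10), 15.0, 5.0, 2 * r1)
    assert np.allclose(conc2[10:], c_true / 2, atol=1e-6)


# ---------------------------------------------------------------------- Tofts

@pytest.fixture(scope="module")
def vif():
    spec = PhantomSpec()
    t = np.arange(80) * 5.0
    return t, plasma_concentration(spec, t)


def test_tofts_degenerate_vp_only(vif):
    t, cp = vif
    kt, kep, vp, ok = fit_extended_tofts(0.05 * cp, cp, t)
    assert ok
    assert kt == pytest.approx(0.0, abs=1e-4)
    assert vp == pytest.approx(0.05, abs=1e-4)


def test_tofts_self_consistency_within_2pct(vif):
    t, cp = vif
    ct = tofts_forward(cp, t, 0.1, 0.5, 0.02)
    kt, kep, vp, ok = fit_extended_tofts(ct, cp, t)
    assert ok
    assert kt == pytest.approx(0.1, rel=0.02)
    assert kep == pytest.approx(0.5, rel=0.02)
    assert vp == pytest.approx(0.02, rel=0.02)


def test_tofts_zero_curve_gives_zero_params(vif):
    t, cp = vif
    kt, kep, vp, ok = fit_extended_tofts(np.zeros_like(cp), cp, t)
    assert ok and kt == 0.0 and kep == 0.0 and vp == 0.0


def test_tofts_identifiability_over_random_draws(vif):
    """Noise-free forward curves are recovered across the parameter box."""
    t, cp = vif
    rng = np.random.default_rng(2)
    worst = 0.0
    for _ in range(25):
        kt = 10 ** rng.uniform(-2, 0)       # 0.01..1 min^-1
        kep = 10 ** rng.uniform(-1, 0.7)    # 0.1..5 min^-1
        vp = rng.uniform(0.005, 0.1)
        ct = tofts_forward(cp, t, kt, kep, vp)
        kt_e, kep_e, vp_e, ok = fit_extended_tofts(ct, cp, t)
        assert ok
        worst = max(worst, abs(kt_e - kt) / kt, abs(kep_e - kep) / kep,
                    abs(vp_e - vp) / vp)
    assert worst < 0.05


# ------------------------------------------------------------------ exclusion

def test_exclusion_simple_percentile_rule():
    shape = (6, 6, 6)
    ncbv = np.ones(shape)
    tumor = np.zeros(shape, dtype=bool)
    tumor[4, :, :] = True
    contra = np.zeros(shape, dtype=bool)
    contra[1, :, :] = True
    ncbv[4, 0, 0] = 5.0  # hyperperfused tumor voxel
    res = blood_exclusion_mask(ncbv, None, tumor, contra, np.zeros(shape, bool))
    assert res.thr_ncbv == pytest.approx(1.0)
    assert res.mask[4, 0, 0]
    assert res.mask.sum() == 1


def test_exclusion_empty_when_nothing_above_thresholds():
    shape = (4, 4, 4)
    ncbv = np.ones(shape)
    tumor = np.zeros(shape, dtype=bool)
    tumor[2] = True
    contra = np.zeros(shape, dtype=bool)
    contra[1] = True
    res = blood_exclusion_mask(ncbv, None, tumor, contra, np.zeros(shape, bool))
    assert not res.mask.any()


def test_exclusion_ktrans_rule_and_monotonicity():
    rng = np.random.default_rng(3)
    shape = (8, 8, 8)
    ncbv = np.ones(shape)
    tumor = np.zeros(shape, dtype=bool)
    tumor[4:] = True
    contra = np.zeros(shape, dtype=bool)
    contra[:4] = True
    et = np.zeros(shape, dtype=bool)
    et[6] = True
    ktrans = np.zeros(shape)
    ktrans[et] = rng.uniform(0.05, 0.15, et.sum())
    res = blood_exclusion_mask(ncbv, ktrans, tumor, contra, et)
    assert res.thr_ktrans is not None
    # all ET voxels above the 5th percentile are excluded
    frac_excluded = res.mask[et].mean()
    assert 0.9 < frac_excluded < 1.0
    # raising the threshold can only shrink the mask
    higher = ktrans > np.percentile(ktrans[et], 50)
    assert higher.sum() <= res.mask.sum()


def test_exclusion_skips_ktrans_without_et(caplog):
    shape = (4, 4, 4)
    tumor = np.zeros(shape, dtype=bool)
    tumor[2] = True
    contra = np.zeros(shape, dtype=bool)
    contra[1] = True
    with caplog.at_level("WARNING"):
        res = blood_exclusion_mask(np.ones(shape), np.ones(shape), tumor,
                                   contra, np.zeros(shape, bool))
    assert res.thr_ktrans is None
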