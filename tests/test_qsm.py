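"""QSM chain: unwrapping, masking, field fitting, V-SHARP, dipole inversion."""

import numpy as np
import pytest
from scipy import ndimage

from tizmap.grids import VolumeGrid
from tizmap.phantom import simulate_field, dipole_kernel
from tizmap.physics import larmor_hz
from tizmap.qsm import (
    laplacian_unwrap, prepare_mask, echo_phase_to_field, vsharp,
    dipole_invert_tkd, dipole_invert_iter, fit_r2star,
)


# ------------------------------------------------------------------ unwrapping

def test_unwrap_zero_phase_is_zero():
    assert np.array_equal(laplacian_unwrap(np.zeros((16, 16, 16))), np.zeros((16, 16, 16)))


def test_unwrap_recovers_wrapped_linear_ramp():
    n = 96
    ramp = np.linspace(0, 6 * np.pi, n)[:, None, None] * np.ones((1, 32, 32))
    wrapped = np.angle(np.exp(1j * ramp))
    unwrapped = laplacian_unwrap(wrapped)
    diff = (unwrapped - ramp)[8:-8, 4:-4, 4:-4]
    assert diff.std() < 0.05


def test_unwrap_invariant_to_global_2pi_offset():
    rng = np.random.default_rng(0)
    smooth = ndimage.gaussian_filter(rng.standard_normal((24, 24, 24)), 4) * 8
    w1 = np.angle(np.exp(1j * smooth))
    w2 = np.angle(np.exp(1j * (smooth + 2 * np.pi)))
    assert np.allclose(laplacian_unwrap(w1), laplacian_unwrap(w2), atol=1e-9)


# ----------------------------------------------------------------------- masks

def test_prepare_mask_erosion_and_union():
    brain = np.zeros((24, 24, 24), dtype=bool)
    brain[4:20, 4:20, 4:20] = True
    tumor = np.zeros_like(brain)
    tumor[4:6, 10:12, 10:12] = True  # at the cortex edge, eroded away
    out = prepare_mask(brain, tumor, erosion_mm=3.0, voxel_size_mm=(2, 2, 2))
    assert out[tumor].all()  # union restores eroded tumor voxels
    no_tumor = prepare_mask(brain, np.zeros_like(brain), 3.0, (2, 2, 2))
    assert no_tumor.sum() < brain.sum() and not np.any(no_tumor & ~brain)


def test_prepare_mask_zero_erosion_is_identity():
    brain = np.zeros((10, 10, 10), dtype=bool)
    brain[2:8, 2:8, 2:8] = True
    tumor = np.zeros_like(brain)
    tumor[4, 4, 4] = True
    assert np.array_equal(prepare_mask(brain, tumor, 0.0), brain)


def test_prepare_mask_negative_erosion_rejected():
    with pytest.raises(ValueError):
        prepare_mask(np.ones((4, 4, 4), bool), np.zeros((4, 4, 4), bool), -1.0)


# --------------------------------------------------------------- field fitting

def test_field_fit_exact_on_noiseless_phases(noiseless_phantom, noiseless_spec):
    gt = noiseless_phantom
    f0 = larmor_hz(noiseless_spec.b0_tesla)
    te_s = np.asarray(noiseless_spec.te_ms) / 1000.0
    phases = np.stack([2 * np.pi * f0 * gt.field_ppm.data * 1e-6 * te
                       for te in te_s])
    field = echo_phase_to_field(phases, noiseless_spec.te_ms,
                                noiseless_spec.b0_tesla)
    assert np.abs(field - gt.field_ppm.data).max() < 1e-9


def test_two_echo_closed_form_slope():
    phi = np.zeros((2, 4, 4, 4))
    phi[0], phi[1] = 0.1, 0.5
    te = np.array([10.0, 30.0])
    field = echo_phase_to_field(phi, te, 3.0)
    slope = (0.5 - 0.1) / (0.02)  # rad/s
    assert np.allclose(field, slope / (2 * np.pi * larmor_hz(3.0) * 1e-6))


def test_constant_phase_offset_absorbed_by_intercept():
    rng = np.random.default_rng(1)
    base = rng.standard_normal((4, 8, 8, 8)) * 0.01
    te = np.array([5.0, 10.0, 15.0, 20.0])
    f1 = echo_phase_to_field(base, te, 3.0)
    f2 = echo_phase_to_field(base + 0.7, te, 3.0)
    assert np.allclose(f1, f2, atol=1e-12)


# --------------------------------------------------------------------- V-SHARP

def _ball_mask(n, radius, center=None):
    c = (n - 1) / 2.0 if center is None else center
    g = np.ogrid[0:n, 0:n, 0:n]
    return sum((gi - ci) ** 2 for gi, ci in
               zip(g, np.broadcast_to(c, (3,)))) <= radius**2


def test_vsharp_removes_external_source_field():
    n = 64
    mask = _ball_mask(n, 20)
    chi = np.zeros((n, n, n))
    chi[3, 3, 3] = 50.0  # well-separated external source: harmonic inside
    field = simulate_field(VolumeGrid(chi, (1, 1, 1))).data
    local, vmask = vsharp(field, mask, (1, 1, 1), radii_mm=np.arange(8, 0, -1.0),
                          background="strict")
    in_rms = np.sqrt(np.mean(field[vmask] ** 2))
    out_rms = np.sqrt(np.mean(local[vmask] ** 2))
    assert out_rms < 0.03 * in_rms


def test_vsharp_preserves_internal_dipole_field():
    n = 64
    mask = _ball_mask(n, 24)
    chi = np.zeros((n, n, n))
    c = (n - 1) // 2
    chi[c - 1:c + 2, c - 1:c + 2, c - 1:c + 2] = 0.5
    field = simulate_field(VolumeGrid(chi, (1, 1, 1))).data
    local, vmask = vsharp(field, mask, (1, 1, 1), radii_mm=np.arange(8, 0, -1.0))
    interior = ndimage.binary_erosion(vmask, iterations=4)
    f = field[interior] - field[interior].mean()
    err = local[interior] - local[interior].mean() - f
    assert np.sqrt(np.mean(err**2)) < 0.10 * np.sqrt(np.mean(f**2))


def test_vsharp_zero_field_zero_output():
    mask = _ball_mask(32, 12)
    local, vmask = vsharp(np.zeros((32, 32, 32)), mask, (1, 1, 1),
                          radii_mm=np.arange(6, 0, -1.0))
    assert np.allclose(local, 0.0)
    assert vmask.any() and not np.any(local[~vmask])


def test_vsharp_shrinks_radius_list_for_small_mask(caplog):
    mask = _ball_mask(32, 5)
    with caplog.at_level("WARNING"):
        local, vmask = vsharp(np.ones((32, 32, 32)), mask, (1, 1, 1),
                              radii_mm=np.arange(12, 0, -1.0))
    assert vmask.any()


# ------------------------------------------------------------- dipole inversion

@pytest.fixture(scope="module")
def sphere_phantom():
    n, r, dchi = 64, 8.0, 0.1
    mask = _ball_mask(n, 26)
    chi = np.where(_ball_mask(n, r), dchi, 0.0)
    field = simulate_field(VolumeGrid(chi, (1, 1, 1))).data
    return chi, np.where(mask, field, 0.0), mask, _ball_mask(n, r - 2)


def test_tkd_recovers_sphere_interior(sphere_phantom):
    chi, field, mask, interior = sphere_phantom
    cm = dipole_invert_tkd(field, mask, (1, 1, 1))
    est = cm.chi_ppm[interior].mean() - cm.chi_ppm[mask].mean()
    true = chi[interior].mean() - chi[mask].mean()
    assert est == pytest.approx(true, rel=0.15)


def test_tkd_zero_field_and_linearity(sphere_phantom):
    _, field, mask, _ = sphere_phantom
    z = dipole_invert_tkd(np.zeros_like(field), mask, (1, 1, 1))
    assert np.allclose(z.chi_ppm, 0.0)
    a = dipole_invert_tkd(field, mask, (1, 1, 1)).chi_ppm
    b = dipole_invert_tkd(3.0 * field, mask, (1, 1, 1)).chi_ppm
    assert np.allclose(b, 3.0 * a, atol=1e-10)


def test_tkd_threshold_validation(sphere_phantom):
    _, field, mask, _ = sphere_phantom
    with pytest.raises(ValueError):
        dipole_invert_tkd(field, mask, (1, 1, 1), threshold=0.5)


def test_iterative_matches_truth_and_tkd(sphere_phantom):
    chi, field, mask, interior = sphere_phantom
    it = dipole_invert_iter(field, mask, (1, 1, 1), lam=1e-3, tol=1e-8)
    tkd = dipole_invert_tkd(field, mask, (1, 1, 1))
    est = it.chi_ppm[interior].mean() - it.chi_ppm[mask].mean()
    true = chi[interior].mean() - chi[mask].mean()
    assert est == pytest.approx(true, rel=0.15)
    est_tkd = tkd.chi_ppm[interior].mean() - tkd.chi_ppm[mask].mean()
    assert est == pytest.approx(est_tkd, rel=0.10)


def test_iterative_large_lambda_shrinks_to_zero(sphere_phantom):
    _, field, mask, _ = sphere_phantom
    cm = dipole_invert_iter(field, mask, (1, 1, 1), lam=1e6, tol=1e-10)
    assert np.abs(cm.chi_ppm).max() < 1e-4


def test_iterative_zero_field_zero_chi(sphere_phantom):
    _, _, mask, _ = sphere_phantom
    cm = dipole_invert_iter(np.zeros(mask.shape), mask, (1, 1, 1))
    assert np.allclose(cm.chi_ppm, 0.0)


def test_inversions_deterministic(sphere_phantom):
    _, field, mask, _ = sphere_phantom
    a = dipole_invert_iter(field, mask, (1, 1, 1), max_iter=50, tol=1e-6)
    b = dipole_invert_iter(field, mask, (1, 1, 1), max_iter=50, tol=1e-6)
    assert np.array_equal(a.chi_ppm, b.chi_ppm)


# ----------------------------------------------------------------------- R2*

def test_r2star_exact_on_monoexponential():
    te = np.array([5.0, 10.0, 20.0, 40.0])
    r2s, m0 = 25.0, 2.0
    mags = np.stack([np.full((4, 4, 4), m0 * np.exp(-r2s * t / 1000.0))
                     for t in te])
    est, s0 = fit_r2star(mags, te)
    assert np.abs(est - r2s).max() < 1e-9
    assert np.abs(s0 - m0).max() < 1e-9


def test_r2star_constant_magnitude_is_zero():
    mags = np.ones((3, 4, 4, 4))
    est, _ = fit_r2star(mags, np.array([5.0, 10.0, 15.0]))
    assert np.allclose(est, 0.0)


def test_r2star_noisy_phantom_wm_error(default_phantom, default_spec):
    from tizmap.phantom import simulate_gre

    gre = simulate_gre(default_phantom, default_spec)
    est, _ = fit_r2star(gre.magnitude, gre.te_ms)
    wm = default_phantom.labels.data == 1
    true = default_phantom.r2star_map.data[wm]
    err = np.abs(est[wm] - true)
    assert np.median(err) < 1.0  # s^-1


# ------------------------------------------------------------------ full loop

def test_full_loop_recovers_chi(qsm_loop):
    """Noiseless phantom -> unwrap -> field -> V-SHARP -> inversion -> chi."""
    gt, fields, chis = qsm_loop
    core = ndimage.binary_erosion(fields.vsharp_mask, iterations=2)
    truth = gt.chi_total.data
    rmses = {}
    for tag, cm in chis.items():
        a = cm.chi_ppm[core] - cm.chi_ppm[core].mean()
        b = truth[core] - truth[core].mean()
        rmses[tag] = np.sqrt(np.mean((a - b) ** 2))
    assert min(rmses.values()) < 0.01
    assert max(rmses.values()) < 0.015


def test_mask_monotonicity(qsm_loop):
    gt, fields, _ = qsm_loop
    brain = gt.labels.data > 0
    tumor = gt.labels.mask("ed", "ncr", "et", "tiz")
    assert not np.any(fields.vsharp_mask & ~fields.analysis_mask)
    assert not np.any(fields.analysis_mask & ~(brain | tumor))


def test_per_echo_reconstruction_agrees_with_joint_fit(noiseless_phantom,
                                                       noiseless_gre):
    """Averaging per-echo chi maps tracks the joint multi-echo fit."""
    from tizmap import qsm

    gt = noiseless_phantom
    brain = gt.labels.data > 0
    tumor = gt.labels.mask("ed", "ncr", "et", "tiz")
    _, chis_pe = qsm.reconstruct_chi(noiseless_gre, brain, tumor,
                                     algorithms=("tkd",), per_echo=True)
    _, chis = qsm.reconstruct_chi(noiseless_gre, brain, tumor,
                                  algorithms=("tkd",))
    m = chis["tkd"].mask
    core = ndimage.binary_erosion(m, iterations=2)
    truth = noiseless_phantom.chi_total.data
    a = chis_pe["tkd"].chi_ppm[core] - chis_pe["tkd"].chi_ppm[core].mean()
    b = truth[core] - truth[core].mean()
    assert np.sqrt(np.mean((a - b) ** 2)) < 0.015
    diff = chis_pe["tkd"].chi_ppm[core] - chis["tkd"].chi_ppm[core]
    assert np.sqrt(np.mean((diff - diff.mean()) ** 2)) < 0.01
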