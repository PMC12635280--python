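"""DSC perfusion (nCBV), DCE permeability (Ktrans) and blood-voxel exclusion.

The perfusion pathway converts the DSC bolus passage to delta-R2*, picks an
arterial input function from vessel voxels, applies a Boxerman-form leakage
correction, computes CBV as an AUC ratio against the AIF and normalizes it
to the contralateral normal-appearing white matter (nCBV).  The
permeability pathway fits T1 from variable-flip-angle baselines, converts
the DCE series to tracer concentration and fits the extended Tofts model.
Voxels dominated by blood are excluded from later susceptibility analysis
by two per-subject percentile thresholds: the 95th percentile of nCBV over
the contralateral (mirror) tumor region, and the 5th percentile of Ktrans
over the contrast-enhancing tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares

__all__ = [
    "PerfusionResult",
    "PermeabilityResult",
    "BloodExclusionMask",
    "dsc_to_delta_r2star",
    "select_aif",
    "leakage_correct",
    "compute_cbv",
    "normalize_cbv",
    "vfa_t1_fit",
    "dce_to_concentration",
    "fit_extended_tofts",
    "fit_tofts_map",
    "blood_exclusion_mask",
]

log = logging.getLogger(__name__)


@dataclass
class PerfusionResult:
    delta_r2star_series: np.ndarray  # (n_frames, nx, ny, nz), s^-1
    aif_curve: np.ndarray
    times_s: np.ndarray
    cbv_map: np.ndarray
    ncbv_map: np.ndarray
    leakage_k2_map: np.ndarray


@dataclass
class PermeabilityResult:
    t10_map_ms: np.ndarray
    vif_curve: np.ndarray
    times_s: np.ndarray
    ktrans_map: np.ndarray  # min^-1
    kep_map: np.ndarray  # min^-1
    vp_map: np.ndarray
    fit_flags: np.ndarray  # True where the fit is valid


@dataclass
class BloodExclusionMask:
    mask: np.ndarray  # True = exclude
    thr_ncbv: float
    thr_ktrans: float | None = None
    notes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# DSC pathway

def dsc_to_delta_r2star(series: np.ndarray, te_ms: float,
                        baseline_frames: int) -> np.ndarray:
    """delta-R2*(t) = -ln(S(t)/S0)/TE with S0 the pre-bolus mean.

    Non-finite values (from S <= 0) are set to 0.
    """
    if baseline_frames < 3:
        raise ValueError("need at least 3 baseline frames")
    s = np.asarray(series, dtype=float)
    s0 = s[:baseline_frames].mean(axis=0)
    te_s = te_ms / 1000.0
    with np.errstate(divide="ignore", invalid="ignore"):
        dr2s = -np.log(s / s0[None]) / te_s
    bad = ~np.isfinite(dr2s)
    if bad.any():
        log.warning("dsc_to_delta_r2star: %d non-finite samples zeroed", bad.sum())
        dr2s[bad] = 0.0
    return dr2s


def select_aif(delta_r2star_series: np.ndarray, vessel_mask: np.ndarray,
               k: int = 5) -> np.ndarray:
    """Average of the k vessel voxels with the largest peak delta-R2*.

    Ties broken by earlier peak time, then lexicographic voxel index.
    """
    vm = np.asarray(vessel_mask, dtype=bool)
    if not vm.any():
        raise ValueError("vessel mask is empty")
    idx = np.argwhere(vm)
    curves = delta_r2star_series[:, vm.nonzero()[0], vm.nonzero()[1], vm.nonzero()[2]]
    peaks = curves.max(axis=0)
    peak_times = curves.argmax(axis=0)
    n = idx.shape[0]
    if k > n:
        log.warning("select_aif: k=%d > %d vessel voxels; using all", k, n)
        k = n
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], peak_times, -peaks))
    return curves[:, order[:k]].mean(axis=1)


def leakage_correct(delta_r2star_series: np.ndarray,
                    nonenhancing_reference_mask: np.ndarray,
                    times_s: np.ndarray,
                    fit_mask: np.ndarray | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Boxerman-style leakage correction.

    Per voxel, fits ``dR2*(t) ~ K1 * Rbar(t) - K2 * int_0^t Rbar`` against
    the mean curve ``Rbar`` of non-enhancing reference tissue, and returns
    ``(corrected_series, k2_map)`` with ``corrected = dR2* + K2 * int Rbar``.
    """
    ref_mask = np.asarray(nonenhancing_reference_mask, dtype=bool)
    if not ref_mask.any():
        raise ValueError("reference mask is empty")
    dr2s = np.asarray(delta_r2star_series, dtype=float)
    rbar = dr2s[:, ref_mask].mean(axis=1)
    int_rbar = cumulative_trapezoid(rbar, times_s, initial=0.0)
    X = np.stack([rbar, -int_rbar], axis=1)  # (n_frames, 2)
    gram = X.T @ X
    if np.linalg.matrix_rank(gram) < 2:
        raise ValueError("degenerate reference curve; cannot fit leakage model")
    shape = dr2s.shape[1:]
    if fit_mask is None:
        fit_mask = np.ones(shape, dtype=bool)
    fm = np.asarray(fit_mask, dtype=bool)
    y = dr2s[:, fm]  # (n_frames, n_vox)
    coef = np.linalg.solve(gram, X.T @ y)  # (2, n_vox)
    k2 = np.zeros(shape)
    k2[fm] = coef[1]
    corrected = dr2s + k2[None] * int_rbar[:, None, None, None]
    return corrected, k2


def compute_cbv(corrected_series: np.ndarray, aif_curve: np.ndarray,
                times_s: np.ndarray) -> np.ndarray:
    """CBV = AUC(tissue delta-R2*) / AUC(AIF), trapezoidal, clipped at 0."""
    auc_aif = np.trapezoid(aif_curve, times_s)
    if auc_aif <= 0:
        raise ValueError("AIF AUC must be > 0")
    auc = np.trapezoid(corrected_series, times_s, axis=0)
    return np.clip(auc / auc_aif, 0.0, None)


def normalize_cbv(cbv_map: np.ndarray, contralateral_nawm_mask: np.ndarray
                  ) -> np.ndarray:
    """nCBV = CBV / median(CBV over contralateral NAWM)."""
    m = np.asarray(contralateral_nawm_mask, dtype=bool)
    if not m.any():
        raise ValueError("NAWM mask is empty")
    med = np.median(cbv_map[m])
    if med <= 0:
        raise ValueError("median CBV over NAWM must be > 0")
    return cbv_map / med


# ---------------------------------------------------------------------------
# DCE pathway

def vfa_t1_fit(vfa_volumes: list[np.ndarray], flip_angles_deg, tr_ms: float,
               t1_clip_ms: tuple[float, float] = (1.0, 10000.0)
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearized SPGR (DESPOT1) T1 fit from variable-flip-angle volumes.

    Fits ``S/sin(a) = E1 * S/tan(a) + M0 (1 - E1)`` across flip angles;
    ``T1 = -TR / ln(slope)``.  Returns ``(t10_ms, m0, flags)`` where flags
    mark voxels with a non-physical slope (clipped to the T1 bounds).
    """
    fas = np.deg2rad(np.asarray(flip_angles_deg, dtype=float))
    if fas.size < 2 or np.unique(fas).size < 2:
        raise ValueError("need >= 2 distinct flip angles")
    vols = np.stack([np.asarray(v, dtype=float) for v in vfa_volumes])
    y = vols / np.sin(fas)[:, None, None, None]
    x = vols / np.tan(fas)[:, None, None, None]
    xm = x.mean(0)
    ym = y.mean(0)
    var = ((x - xm) ** 2).mean(0)
    cov = ((x - xm) * (y - ym)).mean(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(var > 0, cov / var, np.nan)
    flags = ~np.isfinite(slope) | (slope <= 0) | (slope >= 1)
    slope_safe = np.clip(slope, 1e-9, 1.0 - 1e-9)
    with np.errstate(divide="ignore"):
        t1 = -tr_ms / np.log(slope_safe)
    t1 = np.where(np.isfinite(t1), t1, t1_clip_ms[1])
    flags |= (t1 <= t1_clip_ms[0]) | (t1 >= t1_clip_ms[1])
    t1 = np.clip(t1, t1_clip_ms[0], t1_clip_ms[1])
    e1 = np.exp(-tr_ms / t1)
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = np.where(flags, 0.0, (ym - e1 * xm) / (1.0 - e1))
    return t1, m0, flags


def dce_to_concentration(series: np.ndarray, t10_map_ms: np.ndarray,
                         flip_angle_deg: float, tr_ms: float, r1: float,
                         baseline_frames: int = 5) -> np.ndarray:
    """Invert the SPGR equation per frame for T1(t); C = (R1(t) - R10)/r1.

    Output in mM, clipped at 0.
    """
    s = np.asarray(series, dtype=float)
    t10 = np.asarray(t10_map_ms, dtype=float)
    if np.any(t10 <= 0):
        raise ValueError("t10 must be positive")
    a = np.deg2rad(flip_angle_deg)
    e10 = np.exp(-tr_ms / t10)
    s0 = s[:baseline_frames].mean(axis=0)
    # scale M0 sin(a) from the baseline signal and baseline T1
    denom0 = (1.0 - e10 * np.cos(a))
    with np.errstate(divide="ignore", invalid="ignore"):
        msin = s0 * denom0 / (1.0 - e10)
        ratio = np.where(msin > 0, s / msin[None], 0.0)
    # S/(M0 sin a) = (1-E1)/(1-E1 cos a)  =>  E1 = (1-ratio)/(1-ratio cos a)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (1.0 - ratio) / (1.0 - ratio * np.cos(a))
    e1 = np.clip(e1, 1e-9, 1.0 - 1e-9)
    r1_t = -np.log(e1) / (tr_ms / 1000.0)  # s^-1
    r10 = 1.0 / (t10 / 1000.0)
    conc = (r1_t - r10[None]) / r1
    return np.clip(conc, 0.0, None)


def _tofts_model(params, cp, t_min, int_basis):
    ktrans, kep, vp = params
    conv = _exp_conv(cp, t_min, kep)
    return vp * cp + ktrans * conv


def _exp_conv(cp: np.ndarray, t_min: np.ndarray, kep: float) -> np.ndarray:
    """Trapezoidal convolution of cp with exp(-kep t)."""
    n = t_min.size
    out = np.zeros(n)
    ek = np.exp(kep * t_min)  # integrand cp(tau) e^{kep tau}, then * e^{-kep t}
    with np.errstate(over="ignore"):
        g = cp * ek
    if not np.all(np.isfinite(g)):
        # fall back to direct O(n^2) evaluation for large kep*t
        for i in range(n):
            tau = t_min[: i + 1]
            out[i] = np.trapezoid(cp[: i + 1] * np.exp(-kep * (t_min[i] - tau)), tau)
        return out
    cum = cumulative_trapezoid(g, t_min, initial=0.0)
    return cum * np.exp(-kep * t_min)


_TOFTS_STARTS = [(kt, kep, vp)
                 for kt in (0.01, 0.1, 1.0)
                 for kep in (0.1, 1.0)
                 for vp in (0.01, 0.1)]
_TOFTS_BOUNDS = ([0.0, 0.0, 0.0], [5.0, 10.0, 1.0])


def fit_extended_tofts(ct_curve: np.ndarray, vif_curve: np.ndarray,
                       times_s: np.ndarray
                       ) -> tuple[float, float, float, bool]:
    """Bounded multi-start NLLS fit of the extended Tofts model.

    ``Ct(t) = vp Cp(t) + Ktrans int_0^t Cp(tau) exp(-kep (t - tau)) dtau``
    with Ktrans, kep in min^-1.  Returns ``(ktrans, kep, vp, ok)``; a failed
    fit returns zeros with ``ok=False``.  Ties between equally good starts
    resolve to the lowest Ktrans.
    """
    ct = np.asarray(ct_curve, dtype=float)
    cp = np.asarray(vif_curve, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if t.size < 20:
        raise ValueError("need >= 20 frames")
    if not np.any(cp > 0):
        raise ValueError("VIF is identically zero")
    t_min = t / 60.0
    if not np.any(np.abs(ct) > 0):
        return 0.0, 0.0, 0.0, True

    def resid(p):
        return _tofts_model(p, cp, t_min, None) - ct

    best = None
    for start in _TOFTS_STARTS:
        try:
            sol = least_squares(resid, start, bounds=_TOFTS_BOUNDS,
                                method="trf", xtol=1e-10, ftol=1e-10)
        except Exception:  # pragma: no cover - defensive
            continue
        cost = sol.cost
        if best is None or cost < best[0] - 1e-12 or (
                abs(cost - best[0]) <= 1e-12 and sol.x[0] < best[1][0]):
            best = (cost, sol.x)
    if best is None:
        return 0.0, 0.0, 0.0, False
    ktrans, kep, vp = best[1]
    return float(ktrans), float(kep), float(vp), True


def fit_tofts_map(conc_series: np.ndarray, vif_curve: np.ndarray,
                  times_s: np.ndarray, fit_mask: np.ndarray,
                  min_enhance_mm: float = 0.03) -> PermeabilityResult:
    """Voxelwise extended-Tofts fit inside ``fit_mask``.

    Voxels without sustained enhancement (mean concentration over the
    second half of the acquisition below ``min_enhance_mm``) are below the
    detection limit of the kinetic model and are assigned zero parameters
    without running the optimizer; the time-averaged screen is robust to
    single-frame noise excursions.
    """
    shape = conc_series.shape[1:]
    ktrans = np.zeros(shape)
    kep = np.zeros(shape)
    vp = np.zeros(shape)
    flags = np.zeros(shape, dtype=bool)
    fm = np.asarray(fit_mask, dtype=bool)
    half = conc_series.shape[0] // 2
    for ijk in np.argwhere(fm):
        ct = conc_series[:, ijk[0], ijk[1], ijk[2]]
        if ct[half:].mean() < min_enhance_mm:
            flags[tuple(ijk)] = True
            continue
        kt, ke, v, ok = fit_extended_tofts(ct, vif_curve, times_s)
        ktrans[tuple(ijk)] = kt
        kep[tuple(ijk)] = ke
        vp[tuple(ijk)] = v
        flags[tuple(ijk)] = ok
    return PermeabilityResult(
        t10_map_ms=np.zeros(shape), vif_curve=np.asarray(vif_curve),
        times_s=np.asarray(times_s), ktrans_map=ktrans, kep_map=kep,
        vp_map=vp, fit_flags=flags)


# ---------------------------------------------------------------------------
# exclusion mask

def blood_exclusion_mask(ncbv_map: np.ndarray, ktrans_map: np.ndarray | None,
                         tumor_mask: np.ndarray,
                         contralateral_tumor_mask: np.ndarray,
                         et_mask: np.ndarray,
                         ktrans_valid: np.ndarray | None = None
                         ) -> BloodExclusionMask:
    """Percentile-threshold exclusion of blood-dominated voxels.

    * nCBV rule: threshold = 95th percentile of nCBV over the mirror of the
      tumor mask; tumor voxels above it are excluded.
    * Ktrans rule: threshold = 5th percentile of Ktrans over contrast-
      enhancing tissue (successfully fitted voxels only); any voxel with a
      valid Ktrans above it is excluded.
    """
    tumor = np.asarray(tumor_mask, dtype=bool)
    contra = np.asarray(contralateral_tumor_mask, dtype=bool)
    if not contra.any():
        raise ValueError("contralateral tumor mask is empty")
    thr_ncbv = float(np.percentile(ncbv_map[contra], 95))
    mask = tumor & (ncbv_map > thr_ncbv)

    thr_ktrans: float | None = None
    notes: dict = {}
    et = np.asarray(et_mask, dtype=bool)
    if ktrans_map is None or not et.any():
        log.warning("blood exclusion: no Ktrans/ET input; nCBV-only mode")
        notes["ktrans_rule"] = "skipped"
    else:
        valid = np.ones(et.shape, dtype=bool) if ktrans_valid is None \
            else np.asarray(ktrans_valid, dtype=bool)
        sel = et & valid
        if not sel.any():
            log.warning("blood exclusion: no valid ET Ktrans fits; nCBV-only mode")
            notes["ktrans_rule"] = "skipped"
        else:
            thr_ktrans = float(np.percentile(ktrans_map[sel], 5))
            mask = mask | (valid & (ktrans_map > thr_ktrans))
    return BloodExclusionMask(mask, thr_ncbv, thr_ktrans, notes)
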