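"""Symmetric digital tumor-brain phantom.

The phantom is an ellipsoidal "head" (GM shell, WM core, mirrored ventricles
and subcortical nuclei, a midline venous sinus) that is exactly
mirror-symmetric about the mid-sagittal index plane, plus a one-sided tumor
complex: an edema shell (ED) containing a contrast-enhancing rim (ET), a
necrotic core (NCR) and a planted high-iron / low-myelin infiltration pocket
(the TIZ ground truth) inside the edema.  Every voxel carries a paramagnetic
and a diamagnetic source susceptibility; the same static-dephasing forward
model used by the decomposition stage links those sources to R2*, so
sub-voxel source recovery is exact by construction in the noiseless limit.

Simulated acquisitions:

* multi-echo gradient-echo (magnitude + phase per echo) driven by the
  dipole-convolved field of the total susceptibility,
* a DSC bolus-passage series driven by a gamma-variate arterial curve with
  a Boxerman-form leakage term in enhancing tumor,
* a DCE series + variable-flip-angle baselines driven by the extended Tofts
  model with nonzero transfer constant confined to enhancing tumor.

All randomness is drawn from one seeded generator; identical spec + seed
gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grids import DynamicSeries, LabelMap, MultiEchoGRE, VolumeGrid
from .physics import kappa_static_dephasing, larmor_hz, R1_RELAXIVITY

__all__ = [
    "LABEL_CODES",
    "TissueParams",
    "PhantomSpec",
    "GroundTruth",
    "build_labels",
    "assign_sources",
    "simulate_field",
    "simulate_gre",
    "simulate_dsc",
    "simulate_dce",
    "generate_phantom",
]

LABEL_CODES: dict[str, int] = {
    "background": 0,
    "wm": 1,
    "gm": 2,
    "csf": 3,
    "subcortical": 4,
    "vessel": 5,
    "ed": 6,
    "ncr": 7,
    "et": 8,
    "tiz": 9,
}

TUMOR_LABELS = ("ed", "ncr", "et", "tiz")


class GeometryError(ValueError):
    """Compartment geometry violates nesting/hemisphere constraints."""


class ConfigurationError(ValueError):
    """A label is missing tissue parameters or a parameter is invalid."""


@dataclass
class TissueParams:
    """Per-label physical parameters.

    c_para/c_dia are the paramagnetic (>=0) and diamagnetic (<=0) source
    susceptibilities in ppm; r2_s_inv the irreversible baseline transverse
    rate (s^-1); m0 equilibrium signal (arbitrary units); t1_ms longitudinal
    relaxation; cbv the blood-volume fraction driving DSC; k2_leak the
    Boxerman leakage rate (s^-1, relative to the reference tissue curve);
    ktrans/ve/vp extended-Tofts parameters (min^-1, fraction, fraction).
    """

    c_para: float = 0.0
    c_dia: float = 0.0
    r2_s_inv: float = 10.0
    m0: float = 1.0
    t1_ms: float = 1000.0
    cbv: float = 0.0
    k2_leak: float = 0.0
    ktrans: float = 0.0
    ve: float = 0.1
    vp: float = 0.0

    def __post_init__(self) -> None:
        if self.c_para < 0:
            raise ConfigurationError("c_para must be >= 0")
        if self.c_dia > 0:
            raise ConfigurationError("c_dia must be <= 0")
        if self.ktrans > 0 and self.ve <= 0:
            raise ConfigurationError("ve must be > 0 when ktrans > 0")


def _default_tissue_params() -> dict[str, TissueParams]:
    # Susceptibility sources are synthetic plausibility values (ppm), chosen
    # so that the PDR ordering WM < ED < GM << TIZ holds by construction.
    return {
        "background": TissueParams(0.0, 0.0, 0.0, 0.0, 1000.0),
        "wm": TissueParams(0.01, -0.05, 15.0, 1.00, 800.0, cbv=0.020),
        "gm": TissueParams(0.03, -0.02, 14.0, 0.85, 1300.0, cbv=0.040),
        "csf": TissueParams(0.0, 0.0, 2.0, 0.70, 4000.0, cbv=0.003),
        "subcortical": TissueParams(0.08, -0.02, 18.0, 0.90, 1100.0, cbv=0.040),
        "vessel": TissueParams(0.05, -0.01, 20.0, 0.80, 1600.0, cbv=1.0, vp=1.0),
        "ed": TissueParams(0.02, -0.02, 10.0, 1.05, 1500.0, cbv=0.025),
        "ncr": TissueParams(0.05, -0.01, 8.0, 0.75, 2000.0, cbv=0.005),
        "et": TissueParams(
            0.04, -0.02, 12.0, 0.95, 1400.0,
            cbv=0.080, k2_leak=0.05, ktrans=0.10, ve=0.20, vp=0.02,
        ),
        "tiz": TissueParams(0.15, -0.005, 10.0, 1.05, 1500.0, cbv=0.025),
    }


@dataclass
class PhantomSpec:
    """Complete description of the phantom and its simulated acquisitions."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    b0_tesla: float = 3.0
    # eight echoes, TE1/dTE = 5/5 ms
    te_ms: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0)
    noise_sigma: float = 0.02  # complex-noise SD relative to WM m0
    seed: int = 1234

    # geometry, in voxel units relative to the grid center (index (n-1)/2)
    head_radii: tuple[float, float, float] = (26.0, 29.0, 25.0)
    wm_scale: float = 0.82
    tumor_center_offset: tuple[float, float, float] = (14.0, 0.0, 0.0)
    ed_radii: tuple[float, float, float] = (9.0, 9.0, 8.0)
    et_radii: tuple[float, float, float] = (5.0, 5.0, 4.5)
    ncr_radii: tuple[float, float, float] = (2.5, 2.5, 2.0)
    tiz_center_offset: tuple[float, float, float] = (4.5, 4.5, 0.0)  # from ED center
    tiz_radii: tuple[float, float, float] = (4.0, 4.0, 3.5)

    tissue_params: dict[str, TissueParams] = field(default_factory=_default_tissue_params)

    # DSC protocol: TR 1.5 s, 120 frames; gamma-variate bolus after 20 s
    dsc_tr_s: float = 1.5
    dsc_n_frames: int = 120
    dsc_te_ms: float = 30.0
    dsc_t0_s: float = 20.0
    dsc_alpha: float = 3.0
    dsc_beta_s: float = 1.5
    dsc_peak_r2s: float = 60.0  # peak arterial delta-R2* (s^-1)
    dsc_noise_sigma: float = 0.005

    # DCE protocol: 80 frames, 5 s spacing, SPGR FA 15 deg, VFA 5/10/15 deg
    dce_tr_ms: float = 5.0
    dce_n_frames: int = 80
    dce_dt_s: float = 5.0
    dce_flip_deg: float = 15.0
    vfa_flip_deg: tuple[float, ...] = (5.0, 10.0, 15.0)
    dce_t0_s: float = 30.0
    dce_peak_mm: float = 5.0
    dce_noise_sigma: float = 0.002
    r1_relaxivity: float = R1_RELAXIVITY

    def __post_init__(self) -> None:
        te = np.asarray(self.te_ms, dtype=float)
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ConfigurationError("te_ms must be positive and strictly increasing")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")

    @property
    def center(self) -> np.ndarray:
        return (np.asarray(self.grid_shape, dtype=float) - 1.0) / 2.0

    @property
    def kappa(self) -> float:
        return kappa_static_dephasing(self.b0_tesla)


@dataclass
class GroundTruth:
    """Everything downstream stages are graded against."""

    labels: LabelMap
    chi_para: VolumeGrid
    chi_dia: VolumeGrid
    chi_total: VolumeGrid
    field_ppm: VolumeGrid
    r2star_map: VolumeGrid
    m0_map: VolumeGrid
    t1_map_ms: VolumeGrid
    tiz_truth: np.ndarray
    hemisphere_mask: np.ndarray
    kappa: float
    true_params: dict[str, TissueParams]


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center, radii):
        if r <= 0:
            return np.zeros(shape, dtype=bool)
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def build_labels(spec: PhantomSpec) -> LabelMap:
    """Paint the tissue label map; raises :class:`GeometryError` on bad geometry."""
    shape = tuple(spec.grid_shape)
    c = spec.center
    lab = np.zeros(shape, dtype=np.int16)

    head = _ellipsoid(shape, c, spec.head_radii)
    wm_radii = tuple(r * spec.wm_scale for r in spec.head_radii)
    wm = _ellipsoid(shape, c, wm_radii)
    lab[head] = LABEL_CODES["gm"]
    lab[wm] = LABEL_CODES["wm"]

    # mirrored lateral ventricles
    for sx in (-1.0, 1.0):
        vent = _ellipsoid(shape, c + np.array([sx * 5.0, 0.0, 1.0]), (2.5, 8.0, 3.5))
        lab[vent & wm] = LABEL_CODES["csf"]
    # mirrored subcortical nuclei (two per hemisphere)
    for sx in (-1.0, 1.0):
        n1 = _ellipsoid(shape, c + np.array([sx * 10.0, 3.0, 0.0]), (3.0, 4.0, 3.0))
        n2 = _ellipsoid(shape, c + np.array([sx * 9.0, -6.0, -1.0]), (2.5, 3.0, 2.5))
        lab[(n1 | n2) & wm] = LABEL_CODES["subcortical"]
    # midline superior-sagittal-sinus-like vessel: symmetric by construction
    gi, gj, gk = np.ogrid[tuple(slice(0, n) for n in shape)]
    vessel = (
        (np.abs(gi - c[0]) <= 1.0)
        & (np.abs(gk - (c[2] + 0.65 * spec.head_radii[2])) <= 1.5)
        & (np.abs(gj - c[1]) <= 0.55 * spec.head_radii[1])
    )
    lab[vessel & head] = LABEL_CODES["vessel"]

    tumor_any = any(r > 0 for r in spec.ed_radii + spec.et_radii + spec.ncr_radii)
    if tumor_any:
        tc = c + np.asarray(spec.tumor_center_offset, dtype=float)
        ed = _ellipsoid(shape, tc, spec.ed_radii)
        et = _ellipsoid(shape, tc, spec.et_radii)
        ncr = _ellipsoid(shape, tc, spec.ncr_radii)
        if np.any(ncr & ~et) or np.any(et & ~ed):
            raise GeometryError("tumor compartments must be nested NCR < ET < ED")
        if np.any(ed & ~head):
            raise GeometryError("tumor complex extends outside the head")
        mid = (shape[0] - 1) / 2.0
        idx = np.nonzero(ed)[0]
        if idx.size and (idx.min() <= mid):
            raise GeometryError("tumor complex must lie inside one hemisphere")
        lab[ed] = LABEL_CODES["ed"]
        lab[et] = LABEL_CODES["et"]
        lab[ncr] = LABEL_CODES["ncr"]
        tizc = tc + np.asarray(spec.tiz_center_offset, dtype=float)
        tiz = _ellipsoid(shape, tizc, spec.tiz_radii)
        # the infiltration pocket lives strictly inside edema
        lab[tiz & (lab == LABEL_CODES["ed"])] = LABEL_CODES["tiz"]

    return LabelMap(lab, spec.voxel_size_mm, symmetry_axis=0, codes=dict(LABEL_CODES))


def assign_sources(labels: LabelMap, spec: PhantomSpec) -> GroundTruth:
    """Fill per-voxel source susceptibilities, R2*, M0 and T1 from the label table.

    R2* follows the static-dephasing forward model
    ``r2star = r2_baseline + kappa * (c_para + |c_dia|)``.
    """
    lab = labels.data
    present = np.unique(lab)
    code_to_name = {v: k for k, v in LABEL_CODES.items()}
    for code in present:
        name = code_to_name.get(int(code))
        if name is None or name not in spec.tissue_params:
            raise ConfigurationError(f"label code {code} has no tissue parameters")

    shape = lab.shape
    chi_para = np.zeros(shape)
    chi_dia = np.zeros(shape)
    r2star = np.zeros(shape)
    m0 = np.zeros(shape)
    t1 = np.full(shape, 1000.0)
    kappa = spec.kappa
    for code in present:
        tp = spec.tissue_params[code_to_name[int(code)]]
        sel = lab == code
        chi_para[sel] = tp.c_para
        chi_dia[sel] = tp.c_dia
        r2star[sel] = tp.r2_s_inv + kappa * (tp.c_para + abs(tp.c_dia))
        m0[sel] = tp.m0
        t1[sel] = tp.t1_ms

    chi_total = chi_para + chi_dia
    vs = labels.voxel_size_mm
    field = simulate_field(VolumeGrid(chi_total, vs), spec)
    mid = (shape[0] - 1) / 2.0
    gi = np.arange(shape[0], dtype=float).reshape(-1, 1, 1)
    hemisphere = np.broadcast_to(gi > mid, shape).copy()
    return GroundTruth(
        labels=labels,
        chi_para=VolumeGrid(chi_para, vs),
        chi_dia=VolumeGrid(chi_dia, vs),
        chi_total=VolumeGrid(chi_total, vs),
        field_ppm=field,
        r2star_map=VolumeGrid(r2star, vs),
        m0_map=VolumeGrid(m0, vs),
        t1_map_ms=VolumeGrid(t1, vs),
        tiz_truth=lab == LABEL_CODES["tiz"],
        hemisphere_mask=hemisphere,
        kappa=kappa,
        true_params=dict(spec.tissue_params),
    )


def dipole_kernel(shape, voxel_size_mm) -> np.ndarray:
    """Fourier-domain dipole kernel D(k) = 1/3 - kz^2/|k|^2 with D(0) = 0.

    Axis 2 is the B0 axis; zero frequency at index 0.
    """
    ks = [np.fft.fftfreq(n, d=d) for n, d in zip(shape, voxel_size_mm)]
    kx, ky, kz = np.meshgrid(*ks, indexing="ij", sparse=True)
    k2 = kx**2 + ky**2 + kz**2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - kz**2 / k2
    d[k2 == 0] = 0.0
    return d


def simulate_field(chi_total: VolumeGrid, spec: PhantomSpec | None = None) -> VolumeGrid:
    """Dipole-convolve a susceptibility distribution (ppm) into a field map (ppm)."""
    chi = np.asarray(chi_total.data, dtype=float)
    if not np.all(np.isfinite(chi)):
        raise ValueError("chi_total must be finite")
    d = dipole_kernel(chi.shape, chi_total.voxel_size_mm)
    field = np.fft.ifftn(d * np.fft.fftn(chi)).real
    return chi_total.like(field)


def simulate_gre(gt: GroundTruth, spec: PhantomSpec) -> MultiEchoGRE:
    """Multi-echo complex GRE signal with seeded complex Gaussian noise."""
    if spec.noise_sigma < 0:
        raise ConfigurationError("noise_sigma must be >= 0")
    te_s = np.asarray(spec.te_ms, dtype=float) / 1000.0
    f0 = larmor_hz(spec.b0_tesla)
    m0 = gt.m0_map.data
    r2s = gt.r2star_map.data
    phase_rate = 2.0 * np.pi * f0 * gt.field_ppm.data * 1e-6  # rad/s
    echoes = np.empty((te_s.size,) + m0.shape, dtype=np.complex128)
    for k, te in enumerate(te_s):
        echoes[k] = m0 * np.exp(-r2s * te) * np.exp(1j * phase_rate * te)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        m0_wm = spec.tissue_params["wm"].m0
        sd = spec.noise_sigma * m0_wm
        noise = rng.standard_normal(echoes.shape) + 1j * rng.standard_normal(echoes.shape)
        echoes = echoes + sd * noise
    return MultiEchoGRE(echoes, np.asarray(spec.te_ms, dtype=float),
                        spec.b0_tesla, spec.voxel_size_mm)


def gamma_variate(t_s: np.ndarray, t0: float, alpha: float, beta: float,
                  peak: float) -> np.ndarray:
    """Gamma-variate bolus curve scaled to the requested peak amplitude.

    Peak occurs at ``t0 + alpha*beta``.
    """
    t = np.asarray(t_s, dtype=float)
    dt = np.clip(t - t0, 0.0, None)
    raw = dt**alpha * np.exp(-dt / beta)
    raw_peak = (alpha * beta) ** alpha * np.exp(-alpha)
    return peak * raw / raw_peak


def reference_delta_r2s(spec: PhantomSpec, labels: LabelMap,
                        times_s: np.ndarray) -> np.ndarray:
    """Mean DSC delta-R2* curve over non-enhancing brain (WM + GM)."""
    ca = gamma_variate(times_s, spec.dsc_t0_s, spec.dsc_alpha, spec.dsc_beta_s,
                       spec.dsc_peak_r2s)
    n_wm = int(np.count_nonzero(labels.data == LABEL_CODES["wm"]))
    n_gm = int(np.count_nonzero(labels.data == LABEL_CODES["gm"]))
    cbv_wm = spec.tissue_params["wm"].cbv
    cbv_gm = spec.tissue_params["gm"].cbv
    mean_cbv = (n_wm * cbv_wm + n_gm * cbv_gm) / max(n_wm + n_gm, 1)
    return mean_cbv * ca


def simulate_dsc(labels: LabelMap, spec: PhantomSpec) -> tuple[DynamicSeries, dict]:
    """DSC bolus passage.  Returns the series and a ground-truth sidecar.

    Tissue ``dR2*(t) = cbv_label * Ca(t)``; enhancing tumor additionally
    loses signal recovery through a Boxerman-form leakage term
    ``- k2_leak * integral(reference curve)``, which the leakage-correction
    stage is expected to undo.
    """
    times = np.arange(spec.dsc_n_frames) * spec.dsc_tr_s
    ca = gamma_variate(times, spec.dsc_t0_s, spec.dsc_alpha, spec.dsc_beta_s,
                       spec.dsc_peak_r2s)
    ref = reference_delta_r2s(spec, labels, times)
    int_ref = _cumtrapz(ref, times)

    lab = labels.data
    code_to_name = {v: k for k, v in LABEL_CODES.items()}
    te_s = spec.dsc_te_ms / 1000.0
    frames = np.empty((times.size,) + lab.shape)
    truth_cbv: dict[str, float] = {}
    truth_k2: dict[str, float] = {}
    dr2s_by_label = {}
    for code in np.unique(lab):
        name = code_to_name[int(code)]
        tp = spec.tissue_params[name]
        curve = tp.cbv * ca - tp.k2_leak * int_ref
        dr2s_by_label[int(code)] = curve
        truth_cbv[name] = tp.cbv
        truth_k2[name] = tp.k2_leak
    s0 = np.zeros(lab.shape)
    for code, curve in dr2s_by_label.items():
        s0[lab == code] = spec.tissue_params[code_to_name[code]].m0
    for i, t in enumerate(times):
        atten = np.ones(lab.shape)
        for code, curve in dr2s_by_label.items():
            atten[lab == code] = np.exp(-te_s * curve[i])
        frames[i] = s0 * atten
    if spec.dsc_noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        frames = frames + spec.dsc_noise_sigma * rng.standard_normal(frames.shape)
    series = DynamicSeries(frames, times, te_ms=spec.dsc_te_ms,
                           voxel_size_mm=spec.voxel_size_mm)
    sidecar = {"true_cbv": truth_cbv, "true_k2_leak": truth_k2,
               "arterial_curve": ca, "reference_curve": ref}
    return series, sidecar


def plasma_concentration(spec: PhantomSpec, times_s: np.ndarray) -> np.ndarray:
    """Analytic plasma (vascular) tracer curve for DCE: bolus + recirculation."""
    t = np.asarray(times_s, dtype=float)
    bolus = gamma_variate(t, spec.dce_t0_s, 2.0, 12.0, spec.dce_peak_mm)
    dt = np.clip(t - spec.dce_t0_s, 0.0, None)
    recirc = 0.8 * (1.0 - np.exp(-dt / 30.0)) * np.exp(-dt / 600.0)
    return bolus + recirc


def tofts_forward(cp: np.ndarray, times_s: np.ndarray, ktrans_per_min: float,
                  kep_per_min: float, vp: float) -> np.ndarray:
    """Extended Tofts tissue concentration by trapezoidal convolution."""
    t_min = np.asarray(times_s, dtype=float) / 60.0
    n = t_min.size
    ct = np.zeros(n)
    if ktrans_per_min > 0:
        # exponential-kernel convolution, trapezoidal, O(n^2)
        for i in range(n):
            tau = t_min[: i + 1]
            integrand = cp[: i + 1] * np.exp(-kep_per_min * (t_min[i] - tau))
            ct[i] = ktrans_per_min * np.trapezoid(integrand, tau)
    return vp * cp + ct


def _spgr_signal(m0, t1_ms, tr_ms, flip_deg):
    e1 = np.exp(-tr_ms / t1_ms)
    a = np.deg2rad(flip_deg)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def simulate_dce(labels: LabelMap, spec: PhantomSpec
                 ) -> tuple[DynamicSeries, list[VolumeGrid], dict]:
    """DCE dynamic series + VFA baselines.  Returns (series, vfa_volumes, sidecar)."""
    times = np.arange(spec.dce_n_frames) * spec.dce_dt_s
    cp = plasma_concentration(spec, times)
    lab = labels.data
    code_to_name = {v: k for k, v in LABEL_CODES.items()}

    ct_by_label: dict[int, np.ndarray] = {}
    truth: dict[str, dict[str, float]] = {}
    for code in np.unique(lab):
        name = code_to_name[int(code)]
        tp = spec.tissue_params[name]
        if tp.ktrans > 0 and tp.ve <= 0:
            raise ConfigurationError(f"ve must be > 0 for label {name}")
        kep = tp.ktrans / tp.ve if tp.ktrans > 0 else 0.0
        ct_by_label[int(code)] = tofts_forward(cp, times, tp.ktrans, kep, tp.vp)
        truth[name] = {"ktrans": tp.ktrans, "kep": kep, "vp": tp.vp, "ve": tp.ve}

    m0 = np.zeros(lab.shape)
    t10 = np.full(lab.shape, 1000.0)
    for code in np.unique(lab):
        tp = spec.tissue_params[code_to_name[int(code)]]
        m0[lab == code] = tp.m0
        t10[lab == code] = tp.t1_ms

    frames = np.empty((times.size,) + lab.shape)
    r1 = spec.r1_relaxivity
    for i in range(times.size):
        ct_vol = np.zeros(lab.shape)
        for code, ct in ct_by_label.items():
            ct_vol[lab == code] = ct[i]
        r1_t = 1.0 / (t10 / 1000.0) + r1 * ct_vol  # s^-1
        with np.errstate(divide="ignore"):
            t1_t_ms = np.where(r1_t > 0, 1000.0 / r1_t, 1e9)
        frames[i] = _spgr_signal(m0, t1_t_ms, spec.dce_tr_ms, spec.dce_flip_deg)
    vfa = [VolumeGrid(_spgr_signal(m0, t10, spec.dce_tr_ms, fa), spec.voxel_size_mm)
           for fa in spec.vfa_flip_deg]
    if spec.dce_noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 2)
        frames = frames + spec.dce_noise_sigma * rng.standard_normal(frames.shape)
        vfa = [v.like(v.data + spec.dce_noise_sigma
                      * rng.standard_normal(v.data.shape)) for v in vfa]
    series = DynamicSeries(frames, times, tr_ms=spec.dce_tr_ms,
                           flip_angle_deg=spec.dce_flip_deg,
                           voxel_size_mm=spec.voxel_size_mm)
    sidecar = {"true_tofts": truth, "plasma_curve": cp,
               "flip_angles_deg": list(spec.vfa_flip_deg)}
    return series, vfa, sidecar


def _cumtrapz(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    from scipy.integrate import cumulative_trapezoid

    return cumulative_trapezoid(y, x, initial=0.0)


def generate_phantom(spec: PhantomSpec | None = None) -> GroundTruth:
    """Convenience: labels + sources for the (default) spec."""
    spec = spec or PhantomSpec()
    return assign_sources(build_labels(spec), spec)


def no_tumor(spec: PhantomSpec) -> PhantomSpec:
    """Copy of ``spec`` with the tumor complex removed (symmetric head only)."""
    return replace(spec, ed_radii=(0.0,) * 3, et_radii=(0.0,) * 3,
                   ncr_radii=(0.0,) * 3, tiz_radii=(0.0,) * 3)
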